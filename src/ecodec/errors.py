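"""Exception hierarchy used across the pipeline."""


class EcodecError(Exception):
    """Base class for all pipeline errors."""


class FormatError(EcodecError):
    """A file or container does not follow the documented layout."""


class ConsistencyError(EcodecError):
    """Metadata and data disagree (rates, durations, event times, names)."""


class ParameterError(EcodecError, ValueError):
    """An argument or configuration value is outside its admissible range."""


class DataError(EcodecError):
    """Signal content violates a precondition (non-finite values, empty input)."""


class ContractError(EcodecError):
    """Two pipeline objects that must share a manifest do not."""


class LeakageError(EcodecError):
    """An evaluation span overlaps the data a model was trained on."""
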