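"""Recording-session container, on-disk format, and pipeline configuration.

A *session* bundles the raw multichannel cortical-surface (ECoG) recording, the
raw multichannel EMG recording, the behavioural event log, and the electrode
grid geometry.  On disk a session is a directory of plain-text files:

``ecog.csv``
    one column per ECoG channel (header row = channel names), one row per sample
``emg.csv``
    one column per muscle (header row = muscle names)
``events.csv``
    columns ``time_s,label``
``meta.json``
    sampling rates, channel/muscle names, grid layout, subject id

All interface times are seconds (floats); sample indices are internal only,
because two sampling rates coexist before and after downsampling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConsistencyError, DataError, FormatError, ParameterError

EVENT_LABELS = (
    "home_press",
    "home_release",
    "knob_grasp",
    "knob_release",
    "go_cue",
    "reward",
)

#: Conventional sensorimotor-rhythm bands (name, low edge Hz, high edge Hz).
DEFAULT_BANDS = (
    ("delta", 1.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 14.0),
    ("beta1", 14.0, 20.0),
    ("beta2", 20.0, 30.0),
    ("gamma1", 30.0, 50.0),
    ("gamma2", 50.0, 90.0),
)


@dataclass(frozen=True)
class ElectrodeLayout:
    """Grid geometry of the ECoG array.

    ``location_of_channel`` maps each channel name to its grid-column index
    (1-based; column #1 is the most caudal, nearest the central sulcus).  The
    mapping is explicit metadata rather than being inferred from geometry.
    """

    n_rows: int
    n_cols: int
    location_of_channel: Mapping[str, int]

    def validate(self, channel_names: Sequence[str]) -> None:
        missing = [c for c in channel_names if c not in self.location_of_channel]
        if missing:
            raise ConsistencyError(f"channels without a grid location: {missing}")
        if self.n_rows * self.n_cols < len(channel_names):
            raise ConsistencyError(
                f"grid {self.n_rows}x{self.n_cols} cannot hold "
                f"{len(channel_names)} channels"
            )
        for ch in channel_names:
            loc = self.location_of_channel[ch]
            if not (1 <= int(loc) <= self.n_cols):
                raise ConsistencyError(f"channel {ch} location {loc} outside grid columns")

    @property
    def locations(self) -> list[int]:
        return list(range(1, self.n_cols + 1))


@dataclass
class RecordingSession:
    """Raw recordings plus events and geometry for one session."""

    ecog: np.ndarray  # [channels x samples]
    emg: np.ndarray  # [muscles x samples]
    rate_ecog: float
    rate_emg: float
    events: list[tuple[float, str]]
    layout: ElectrodeLayout
    channel_names: list[str]
    muscle_names: list[str]
    subject_id: str = "synthetic"

    @property
    def n_channels(self) -> int:
        return self.ecog.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.emg.shape[0]

    @property
    def duration(self) -> float:
        """Session length in seconds (set by the ECoG trace)."""
        return self.ecog.shape[1] / self.rate_ecog

    def validate(self) -> None:
        if self.ecog.ndim != 2 or self.emg.ndim != 2:
            raise FormatError("ecog and emg must be 2-D [channels x samples]")
        if not np.isfinite(self.ecog).all() or not np.isfinite(self.emg).all():
            raise DataError("signal contains non-finite samples")
        if self.rate_ecog <= 0 or self.rate_emg <= 0:
            raise ParameterError("sampling rates must be positive")
        if len(self.channel_names) != self.ecog.shape[0]:
            raise ConsistencyError("channel_names length != ECoG row count")
        if len(self.muscle_names) != self.emg.shape[0]:
            raise ConsistencyError("muscle_names length != EMG row count")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError("duplicate channel names")
        if len(set(self.muscle_names)) != len(self.muscle_names):
            raise FormatError("duplicate muscle names")
        dur_ecog = self.ecog.shape[1] / self.rate_ecog
        dur_emg = self.emg.shape[1] / self.rate_emg
        if abs(dur_ecog - dur_emg) > 1.0 / min(self.rate_ecog, self.rate_emg) + 1e-9:
            raise ConsistencyError(
                f"ECoG duration {dur_ecog:.4f}s and EMG duration {dur_emg:.4f}s disagree"
            )
        for t, label in self.events:
            if label not in EVENT_LABELS:
                raise FormatError(f"unknown event label {label!r}")
            if not (0.0 <= t <= dur_ecog):
                raise ConsistencyError(
                    f"event {label} at {t} s outside recording [0, {dur_ecog:.3f}] s"
                )
        self.layout.validate(self.channel_names)

    def event_times(self, label: str) -> np.ndarray:
        return np.array([t for t, lab in self.events if lab == label], dtype=float)


@dataclass
class ArdHyper:
    """Hyperparameters of the variational ARD regression.

    ``alpha_prior`` are the Gamma(shape, rate) hyperprior parameters of the
    per-column relevance precisions.  The shape acts as the sparsity knob: a
    column survives the fit only if its squared standardized correlation with
    the residual exceeds roughly 8x the shape, and the precisions of columns
    below that threshold diverge geometrically (factor 1 + 2*shape per
    sweep) until they cross ``prune_threshold`` and the column is removed.
    The default shape 2 retains coefficients above about four standard
    errors; the rate is kept near zero so relevant precisions stay
    data-driven.
    """

    max_iter: int = 500
    tol: float = 1e-6
    prune_threshold: float = 1e8
    alpha_prior: tuple[float, float] = (2.0, 1e-12)
    beta_prior: tuple[float, float] = (1e-6, 1e-6)
    fixed_alpha: float | None = None  # freeze all relevance precisions (ridge mode)

    def validate(self) -> None:
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.tol <= 0 or self.prune_threshold <= 0:
            raise ParameterError("tol and prune_threshold must be positive")
        if any(v <= 0 for v in self.alpha_prior + self.beta_prior):
            raise ParameterError("Gamma hyperprior parameters must be positive")
        if self.fixed_alpha is not None and self.fixed_alpha <= 0:
            raise ParameterError("fixed_alpha must be positive")


@dataclass
class PipelineConfig:
    """All tunable knobs of the decoding pipeline, with field defaults."""

    target_rate: float = 500.0  # Hz, analysis rate after downsampling
    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    zscore_window: float = 1.0  # s, trailing normalisation window
    gauss_width: float = 0.1  # s, total support of the smoothing kernel
    gauss_sigma: float = 0.04  # s, SD of the smoothing kernel
    rectify_before_smooth: bool = True
    emg_cutoff: float = 4.0  # Hz, low-pass for the muscle-activity envelope
    lag_step: float = 0.020  # s, lag grid step (20 ms)
    n_lags: int = 10
    lag_offset: int = 0  # 0: lags 0..(N-1)*step; 1: step..N*step (strictly causal)
    trial_window: tuple[float, float] = (0.5, 1.5)  # (pre, post) s around onset
    k_folds: int = 10
    train_subsets_per_fold: int | None = None  # None -> k_folds - 1
    fit_row_decimation: int = 1  # fit on every d-th design row inside trials
    bidirectional_filters: bool = True
    seed: int = 0
    ard: ArdHyper = field(default_factory=ArdHyper)

    def validate(self) -> None:
        if self.target_rate <= 0:
            raise ParameterError("target_rate must be positive")
        nyq = self.target_rate / 2.0
        prev_high = -math.inf
        prev_low = -math.inf
        for name, low, high in self.bands:
            if not (0 < low < high):
                raise ParameterError(f"band {name}: need 0 < low < high")
            if high >= nyq:
                raise ParameterError(f"band {name}: high edge {high} >= Nyquist {nyq}")
            if low < prev_high - 1e-12 or low < prev_low:
                raise ParameterError("bands must be non-overlapping and ordered by low edge")
            prev_high, prev_low = high, low
        if self.n_lags < 1:
            raise ParameterError("n_lags must be >= 1")
        if self.lag_step <= 0:
            raise ParameterError("lag_step must be positive")
        if self.lag_offset not in (0, 1):
            raise ParameterError("lag_offset must be 0 or 1")
        if self.zscore_window <= 0 or self.gauss_width <= 0 or self.gauss_sigma <= 0:
            raise ParameterError("window and kernel parameters must be positive")
        if self.emg_cutoff <= 0 or self.emg_cutoff >= nyq:
            raise ParameterError("emg_cutoff must lie in (0, target Nyquist)")
        if self.trial_window[0] + self.trial_window[1] <= 0:
            raise ParameterError("trial window must have positive length")
        if self.k_folds < 2:
            raise ParameterError("k_folds must be >= 2")
        n_train = self.train_subsets_per_fold
        if n_train is not None and not (1 <= n_train <= self.k_folds - 1):
            raise ParameterError("train_subsets_per_fold must be in [1, k_folds-1]")
        if self.fit_row_decimation < 1:
            raise ParameterError("fit_row_decimation must be >= 1")
        self.ard.validate()

    @property
    def band_names(self) -> list[str]:
        return [b[0] for b in self.bands]

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "target_rate": self.target_rate,
            "bands": [list(b) for b in self.bands],
            "zscore_window": self.zscore_window,
            "gauss_width": self.gauss_width,
            "gauss_sigma": self.gauss_sigma,
            "rectify_before_smooth": self.rectify_before_smooth,
            "emg_cutoff": self.emg_cutoff,
            "lag_step": self.lag_step,
            "n_lags": self.n_lags,
            "lag_offset": self.lag_offset,
            "trial_window": list(self.trial_window),
            "k_folds": self.k_folds,
            "train_subsets_per_fold": self.train_subsets_per_fold,
            "fit_row_decimation": self.fit_row_decimation,
            "bidirectional_filters": self.bidirectional_filters,
            "seed": self.seed,
            "ard": {
                "max_iter": self.ard.max_iter,
                "tol": self.ard.tol,
                "prune_threshold": self.ard.prune_threshold,
                "alpha_prior": list(self.ard.alpha_prior),
                "beta_prior": list(self.ard.beta_prior),
                "fixed_alpha": self.ard.fixed_alpha,
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        ard_d = dict(d.pop("ard", {}))
        if "alpha_prior" in ard_d:
            ard_d["alpha_prior"] = tuple(ard_d["alpha_prior"])
        if "beta_prior" in ard_d:
            ard_d["beta_prior"] = tuple(ard_d["beta_prior"])
        ard = ArdHyper(**ard_d)
        if "bands" in d:
            d["bands"] = tuple((str(n), float(lo), float(hi)) for n, lo, hi in d["bands"])
        if "trial_window" in d:
            d["trial_window"] = tuple(d["trial_window"])
        cfg = cls(ard=ard, **d)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    def replace(self, **kw) -> "PipelineConfig":
        cfg = replace(self, **kw)
        cfg.validate()
        return cfg


def default_config() -> PipelineConfig:
    """Pipeline configuration with the conventional settings.

    Seven sensorimotor bands, 500 Hz analysis rate, 1 s trailing z-score
    window, Gaussian smoothing (0.1 s support, 40 ms SD), ten 20-ms lags
    (200 ms of history), 10-fold trial-wise cross-validation.
    """
    cfg = PipelineConfig()
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

_SIGNAL_FMT = "%.17g"  # round-trips float64 exactly in decimal text


def write_session(session: RecordingSession, out_dir: str | Path) -> dict[str, Path]:
    """Write a validated session to ``out_dir``; returns the file inventory."""
    session.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "ecog": out / "ecog.csv",
        "emg": out / "emg.csv",
        "events": out / "events.csv",
        "meta": out / "meta.json",
    }
    _write_signal_csv(files["ecog"], session.ecog, session.channel_names)
    _write_signal_csv(files["emg"], session.emg, session.muscle_names)
    ev = pd.DataFrame(session.events, columns=["time_s", "label"])
    ev.to_csv(files["events"], index=False, float_format=_SIGNAL_FMT)
    meta = {
        "subject_id": session.subject_id,
        "rate_ecog": session.rate_ecog,
        "rate_emg": session.rate_emg,
        "channel_names": list(session.channel_names),
        "muscle_names": list(session.muscle_names),
        "n_samples_ecog": int(session.ecog.shape[1]),
        "n_samples_emg": int(session.emg.shape[1]),
        "layout": {
            "n_rows": session.layout.n_rows,
            "n_cols": session.layout.n_cols,
            "location_of_channel": dict(session.layout.location_of_channel),
        },
    }
    files["meta"].write_text(json.dumps(meta, indent=2))
    return files


def _write_signal_csv(path: Path, matrix: np.ndarray, names: Sequence[str]) -> None:
    header = ",".join(names)
    np.savetxt(path, np.asarray(matrix).T, fmt=_SIGNAL_FMT, delimiter=",",
               header=header, comments="")


def _read_signal_csv(path: Path, expected_names: Sequence[str]) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    names = list(df.columns)
    if names != list(expected_names):
        raise FormatError(
            f"{path.name}: columns {names} do not match metadata {list(expected_names)}"
        )
    return np.ascontiguousarray(df.to_numpy(dtype=float).T)


def read_session(session_dir: str | Path) -> RecordingSession:
    """Read and validate a session directory written by :func:`write_session`."""
    d = Path(session_dir)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("rate_ecog", "rate_emg", "channel_names", "muscle_names", "layout"):
        if key not in meta:
            raise FormatError(f"meta.json missing field {key!r}")
    if len(set(meta["channel_names"])) != len(meta["channel_names"]):
        raise FormatError("duplicate channel names in metadata")
    ecog = _read_signal_csv(d / "ecog.csv", meta["channel_names"])
    emg = _read_signal_csv(d / "emg.csv", meta["muscle_names"])
    for key, arr, rate in (("n_samples_ecog", ecog, meta["rate_ecog"]),
                           ("n_samples_emg", emg, meta["rate_emg"])):
        if key in meta and arr.shape[1] != meta[key]:
            raise ConsistencyError(
                f"{key}: metadata declares {meta[key]} samples, file has {arr.shape[1]}"
            )
    events_path = d / "events.csv"
    events: list[tuple[float, str]] = []
    if events_path.exists():
        ev = pd.read_csv(events_path)
        if list(ev.columns) != ["time_s", "label"] and len(ev) > 0:
            raise FormatError("events.csv must have columns time_s,label")
        events = [(float(t), str(lab)) for t, lab in zip(ev.get("time_s", []), ev.get("label", []))]
    lay = meta["layout"]
    layout = ElectrodeLayout(
        n_rows=int(lay["n_rows"]),
        n_cols=int(lay["n_cols"]),
        location_of_channel={k: int(v) for k, v in lay["location_of_channel"].items()},
    )
    session = RecordingSession(
        ecog=ecog,
        emg=emg,
        rate_ecog=float(meta["rate_ecog"]),
        rate_emg=float(meta["rate_emg"]),
        events=events,
        layout=layout,
        channel_names=list(meta["channel_names"]),
        muscle_names=list(meta["muscle_names"]),
        subject_id=str(meta.get("subject_id", "unknown")),
    )
    session.validate()
    return session
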