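"""Lagged design matrices and trial segmentation.

The decoder predicts the muscle envelope at time t from the N most recent
values of every band source on a lag grid of step ``lag_step`` (20 ms by
default, N = 10, i.e. 200 ms of history).  The design matrix is exposed
lazily: rows are materialised on demand from the source matrix, so a long
session never requires the full [rows x M*N] array in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError
from .preprocess import BandSourceSet
from .session_io import PipelineConfig


@dataclass
class DesignMatrix:
    """Lazy view of the lagged feature matrix.

    Row r corresponds to target time ``times[r]``; column c = i * n_lags + j
    holds source i delayed by ``(j + lag_offset) * lag_step`` seconds.  Rows
    are restricted to times where every lag falls in the valid region of the
    sources (``n_dropped`` leading rows are dropped).
    """

    sources: BandSourceSet
    n_lags: int
    lag_step_samples: int
    lag_offset: int
    row0: int  # sample index of row 0 in the source time base
    n_rows: int
    n_dropped: int
    column_index: list[tuple[int, int]] = field(repr=False)  # column -> (source, lag)

    @property
    def n_cols(self) -> int:
        return self.sources.n_sources * self.n_lags

    @property
    def rate(self) -> float:
        return self.sources.rate

    @property
    def times(self) -> np.ndarray:
        return (self.row0 + np.arange(self.n_rows)) / self.rate

    @property
    def source_index(self) -> list[tuple[str, str]]:
        return self.sources.index

    def rows(self, row_ids: np.ndarray, dtype=np.float64) -> np.ndarray:
        """Materialise the given design rows as a dense [len(row_ids) x M*N] block."""
        row_ids = np.asarray(row_ids)
        if row_ids.size and (row_ids.min() < 0 or row_ids.max() >= self.n_rows):
            raise ParameterError("row index out of range")
        m = self.sources.n_sources
        out = np.empty((row_ids.size, m * self.n_lags), dtype=dtype)
        base = self.row0 + row_ids
        for j in range(self.n_lags):
            shift = (j + self.lag_offset) * self.lag_step_samples
            block = self.sources.sources[:, base - shift]  # [M x rows]
            out[:, j::self.n_lags] = block.T
        return out

    def toarray(self, dtype=np.float64) -> np.ndarray:
        return self.rows(np.arange(self.n_rows), dtype=dtype)

    def row_at_time(self, t: float) -> int:
        """Row index whose target time is nearest to t (exact on the grid)."""
        return int(round(t * self.rate)) - self.row0

    def manifest(self) -> dict:
        """Identity of the column layout, for model/feature compatibility checks."""
        return {
            "source_index": list(self.sources.index),
            "n_lags": self.n_lags,
            "lag_step_samples": self.lag_step_samples,
            "lag_offset": self.lag_offset,
            "rate": self.rate,
        }


def build_design_matrix(sources: BandSourceSet, config: PipelineConfig) -> DesignMatrix:
    """Lay out the lagged feature columns for the given sources."""
    config.validate()
    step = config.lag_step * sources.rate
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ParameterError(
            f"lag_step {config.lag_step}s is not a positive multiple of the "
            f"sample period at {sources.rate} Hz"
        )
    step = int(round(step))
    max_shift = (config.n_lags - 1 + config.lag_offset) * step
    first_valid = sources.valid_from_sample
    row0 = first_valid + max_shift
    n_rows = sources.n_samples - row0
    if n_rows <= 0:
        raise DataError("no design rows: sources shorter than history plus warm-up")
    column_index = [(i, j) for i in range(sources.n_sources) for j in range(config.n_lags)]
    return DesignMatrix(
        sources=sources,
        n_lags=config.n_lags,
        lag_step_samples=step,
        lag_offset=config.lag_offset,
        row0=row0,
        n_rows=n_rows,
        n_dropped=row0,
        column_index=column_index,
    )


@dataclass
class TrialSet:
    """Fixed-length windows around trial onsets, as design-row spans."""

    onsets: np.ndarray  # onset time [s] of each kept trial
    starts: np.ndarray  # design row index of each trial's first sample
    n_rows_per_trial: int
    window: tuple[float, float]  # (pre, post) seconds
    n_dropped: int
    alignment: str = "home_release"

    @property
    def n_trials(self) -> int:
        return len(self.starts)

    def span(self, trial: int) -> np.ndarray:
        return self.starts[trial] + np.arange(self.n_rows_per_trial)

    def all_rows(self, decimation: int = 1) -> np.ndarray:
        """Row indices of all trials concatenated (optionally on a coarser grid)."""
        offs = np.arange(0, self.n_rows_per_trial, decimation)
        return (self.starts[:, None] + offs[None, :]).ravel()


def extract_trials(events: list[tuple[float, str]], design: DesignMatrix,
                   window: tuple[float, float],
                   alignment: str = "home_release") -> TrialSet:
    """One trial per alignment event, spanning [onset - pre, onset + post).

    Trials whose window leaves the design matrix (including its invalid
    warm-up region) are dropped and counted.
    """
    pre, post = window
    if pre + post <= 0:
        raise ParameterError("trial window must have positive length")
    onsets = np.array(sorted(t for t, lab in events if lab == alignment), dtype=float)
    if onsets.size == 0:
        raise DataError(f"no trials: no {alignment!r} events present")
    rate = design.rate
    n_per = int(round((pre + post) * rate))
    starts, kept = [], []
    for t in onsets:
        r = int(round((t - pre) * rate)) - design.row0
        if r < 0 or r + n_per > design.n_rows:
            continue
        starts.append(r)
        kept.append(t)
    if not starts:
        raise DataError("no trials: every window falls outside the valid region")
    return TrialSet(
        onsets=np.array(kept),
        starts=np.array(starts, dtype=int),
        n_rows_per_trial=n_per,
        window=(pre, post),
        n_dropped=int(onsets.size - len(starts)),
        alignment=alignment,
    )
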