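"""Trial-wise cross-validated evaluation and continuous-stream assessment.

Accuracy is measured by the Pearson correlation coefficient (CC) between the
actual and predicted muscle-activity envelopes and by the normalised
root-mean-square error

    nRMSE = sqrt(mean((yhat - y)^2)) / (y_max - y_min),

where y_max and y_min are taken over the *actual* trace of the evaluation
span (per trial in trial-wise mode, the whole span in continuous mode).
Negative CC values are retained in all numeric reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, LeakageError, ParameterError
from .features import DesignMatrix, TrialSet
from .preprocess import MuscleActivitySet
from .session_io import PipelineConfig
from .slir import SlirModel, accumulate_stats, fit_slir, predict


def correlation(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation; NaN (with a warning upstream) if actual is flat."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.size < 2:
        raise ParameterError("correlation needs two equal-length vectors (n >= 2)")
    a = actual - actual.mean()
    b = predicted - predicted.mean()
    va, vb = a @ a, b @ b
    if va <= 0 or vb <= 0:
        return float("nan")
    return float((a @ b) / math.sqrt(va * vb))


def nrmse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Root-mean-square error normalised by the range of the actual trace."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.size < 1:
        raise ParameterError("nrmse needs two equal-length vectors")
    span = actual.max() - actual.min()
    if span <= 0:
        return float("nan")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)) / span)


def kfold_split(trial_ids: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Random partition of trials into k folds of as-equal-as-possible size.

    Returns an integer fold label per trial; deterministic for a given seed.
    """
    trial_ids = np.asarray(trial_ids)
    n = trial_ids.size
    if k > n:
        raise ParameterError(f"k={k} folds but only {n} trials")
    if k < 2:
        raise ParameterError("need k >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    # contiguous blocks of the permutation; sizes differ by at most one
    bounds = np.linspace(0, n, k + 1).round().astype(int)
    for f in range(k):
        labels[perm[bounds[f]:bounds[f + 1]]] = f
    return labels


@dataclass
class EvalReport:
    """Cross-validation results with per-trial, per-fold and grand summaries."""

    trial_metrics: pd.DataFrame  # columns: fold, muscle, trial, cc, nrmse
    fold_assignment: np.ndarray  # fold label per trial
    k: int
    seed: int
    muscle_names: list[str]
    models: list[SlirModel] = field(default_factory=list, repr=False)

    def fold_summary(self) -> pd.DataFrame:
        """Mean and SD over trials, per (fold, muscle)."""
        return (self.trial_metrics
                .groupby(["fold", "muscle"], sort=True)[["cc", "nrmse"]]
                .agg(["mean", "std"]))

    def muscle_summary(self) -> pd.DataFrame:
        """Grand mean (mean of fold means) and SEM = SD(fold means)/sqrt(k)."""
        fold_means = (self.trial_metrics
                      .groupby(["fold", "muscle"], sort=True)[["cc", "nrmse"]]
                      .mean().reset_index())
        out = {}
        for metric in ("cc", "nrmse"):
            g = fold_means.groupby("muscle", sort=False)[metric]
            out[(metric, "grand_mean")] = g.mean()
            out[(metric, "sem")] = g.std(ddof=1) / np.sqrt(self.k)
        df = pd.DataFrame(out)
        return df.reindex(self.muscle_names)

    def grand_mean_cc(self) -> pd.Series:
        return self.muscle_summary()[("cc", "grand_mean")]

    def to_table(self) -> pd.DataFrame:
        """Report laid out statistic x fold in rows, muscles in columns."""
        fs = self.fold_summary()
        rows = []
        for metric in ("cc", "nrmse"):
            for f in range(self.k):
                cells = {}
                for m in self.muscle_names:
                    mean = fs.loc[(f, m), (metric, "mean")]
                    sd = fs.loc[(f, m), (metric, "std")]
                    cells[m] = f"{mean:.2f}±{sd:.2f}"
                rows.append({"statistic": metric.upper(), "test_set": f + 1, **cells})
            ms = self.muscle_summary()
            avg = {m: f"{ms.loc[m, (metric, 'grand_mean')]:.2f}"
                      f"±{ms.loc[m, (metric, 'sem')]:.3f}"
                   for m in self.muscle_names}
            rows.append({"statistic": metric.upper(), "test_set": "Avg.", **avg})
        return pd.DataFrame(rows)


def cross_validate(design: DesignMatrix, emg: MuscleActivitySet, trials: TrialSet,
                   config: PipelineConfig, seed: int | None = None,
                   keep_models: bool = True) -> EvalReport:
    """Trial-wise k-fold cross-validation of the sparse decoder.

    Each fold fits on the rows of the training-subset trials (every
    ``config.fit_row_decimation``-th row) and is scored on the held-out
    trials at full resolution, per trial and muscle.
    """
    config.validate()
    if emg.rate != design.rate:
        raise ParameterError("EMG envelope rate differs from design-matrix rate")
    seed = config.seed if seed is None else seed
    k = config.k_folds
    labels = kfold_split(np.arange(trials.n_trials), k, seed)
    n_train_subsets = (config.train_subsets_per_fold
                       if config.train_subsets_per_fold is not None else k - 1)
    # design-row-aligned targets: Y[r] is the envelope at design row r
    Y = emg.activity.T[design.row0:design.row0 + design.n_rows]

    rng = np.random.default_rng(seed + 1)
    records = []
    models: list[SlirModel] = []
    for f in range(k):
        train_subsets = [s for s in range(k) if s != f]
        if n_train_subsets < k - 1:
            pick = rng.permutation(len(train_subsets))[:n_train_subsets]
            train_subsets = [train_subsets[i] for i in sorted(pick)]
        train_trials = np.flatnonzero(np.isin(labels, train_subsets))
        test_trials = np.flatnonzero(labels == f)
        sub = TrialSet(onsets=trials.onsets[train_trials],
                       starts=trials.starts[train_trials],
                       n_rows_per_trial=trials.n_rows_per_trial,
                       window=trials.window, n_dropped=0,
                       alignment=trials.alignment)
        train_rows = sub.all_rows(config.fit_row_decimation)
        stats = accumulate_stats(design, Y, train_rows)
        model = fit_slir(design, Y, config.ard, rows=train_rows,
                         muscle_names=emg.muscle_names, stats=stats)
        for t in test_trials:
            span = trials.span(t)
            yhat = predict(model, design, rows=span)
            yact = Y[span]
            for ki, mname in enumerate(emg.muscle_names):
                records.append({
                    "fold": f, "muscle": mname, "trial": int(t),
                    "cc": correlation(yact[:, ki], yhat[:, ki]),
                    "nrmse": nrmse(yact[:, ki], yhat[:, ki]),
                })
        if keep_models:
            models.append(model)
    return EvalReport(
        trial_metrics=pd.DataFrame(records),
        fold_assignment=labels,
        k=k,
        seed=seed,
        muscle_names=list(emg.muscle_names),
        models=models,
    )


def continuous_evaluate(model: SlirModel, design: DesignMatrix,
                        emg: MuscleActivitySet, span: tuple[float, float],
                        session_id: str = "") -> pd.DataFrame:
    """Score a single uninterrupted prediction pass over ``span`` seconds.

    The model must have been trained on different data; an overlap between
    the evaluation span and the model's training span (same session) raises
    :class:`LeakageError`.  Metrics are computed over the whole span.
    """
    t0, t1 = span
    if t1 <= t0:
        raise ParameterError("evaluation span must have positive length")
    if model.train_span is not None:
        sid, tr0, tr1 = model.train_span
        if sid == session_id and not (t1 <= tr0 or t0 >= tr1):
            raise LeakageError(
                f"evaluation span [{t0}, {t1}] s overlaps training span "
                f"[{tr0:.2f}, {tr1:.2f}] s of session {sid!r}"
            )
    r0 = max(design.row_at_time(t0), 0)
    r1 = min(design.row_at_time(t1), design.n_rows)
    if r1 <= r0:
        raise DataError("evaluation span holds no valid design rows")
    rows = np.arange(r0, r1)
    yhat = predict(model, design, rows=rows)
    yact = emg.activity.T[design.row0:design.row0 + design.n_rows][rows]
    out = []
    for ki, name in enumerate(emg.muscle_names):
        out.append({"muscle": name,
                    "cc": correlation(yact[:, ki], yhat[:, ki]),
                    "nrmse": nrmse(yact[:, ki], yhat[:, ki])})
    return pd.DataFrame(out).set_index("muscle")


def time_shift_control(emg: MuscleActivitySet, shift_s: float) -> MuscleActivitySet:
    """Chance-level control: circularly shift the EMG stream in time.

    A shift spanning many trial periods decouples the EMG from the trial
    events (inter-onset jitter randomises the task phase inside each
    evaluation window), so refitting on the shifted targets measures
    chance-level decoding.  This is the appropriate null in an onset-locked
    task: merely permuting trial *identities* leaves both features and
    targets time-locked to the onset, and a decoder can still predict the
    stereotyped across-trial template (see :func:`permute_trial_blocks`).
    """
    shift = int(round(shift_s * emg.rate))
    if shift % emg.activity.shape[1] == 0:
        raise ParameterError("shift must move the stream by a nonzero offset")
    return MuscleActivitySet(activity=np.roll(emg.activity, shift, axis=1),
                             rate=emg.rate, muscle_names=list(emg.muscle_names))


def random_segment_control(emg: MuscleActivitySet, trials: TrialSet,
                           design: DesignMatrix, seed: int) -> MuscleActivitySet:
    """Chance-level control: fill each trial window with a random EMG segment.

    Every onset-aligned trial window receives envelope content drawn from a
    uniformly random position in the session, so the task phase inside each
    window is uniform and no trial-locked structure survives.  Refitting on
    these targets measures chance-level decoding without the residual phase
    clustering a single circular shift can leave on short sessions.
    """
    rng = np.random.default_rng(seed)
    act = emg.activity.copy()
    n = trials.n_rows_per_trial
    n_samples = emg.activity.shape[1]
    for t in range(trials.n_trials):
        dst = trials.starts[t] + design.row0
        src = int(rng.integers(0, n_samples - n))
        act[:, dst:dst + n] = emg.activity[:, src:src + n]
    return MuscleActivitySet(activity=act, rate=emg.rate,
                             muscle_names=list(emg.muscle_names))


def permute_trial_blocks(emg: MuscleActivitySet, trials: TrialSet, design: DesignMatrix,
                         seed: int) -> MuscleActivitySet:
    """Trial-identity shuffle: permute the EMG content of trial windows.

    The envelope samples inside each onset-aligned trial window are swapped
    between trials (windows have identical length).  Because both signals
    remain locked to the trial onset, the cross-validated accuracy on the
    permuted targets estimates the *stereotypy ceiling* — the part of the
    decode explained by the across-trial template alone — rather than
    chance level; compare :func:`time_shift_control`.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(trials.n_trials)
    act = emg.activity.copy()
    n = trials.n_rows_per_trial
    for t in range(trials.n_trials):
        src = trials.starts[perm[t]] + design.row0
        dst = trials.starts[t] + design.row0
        act[:, dst:dst + n] = emg.activity[:, src:src + n]
    return MuscleActivitySet(activity=act, rate=emg.rate,
                             muscle_names=list(emg.muscle_names))
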