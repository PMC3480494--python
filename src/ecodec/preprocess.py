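"""Raw signals -> decoding features.

The cortical pathway is: downsample to the analysis rate, common-average
re-reference, split each channel into the seven sensorimotor-rhythm bands with
bidirectional 4th-order Butterworth filters, normalise each band-passed trace
by a *trailing* 1-s z-score, rectify and smooth with a short Gaussian kernel.
The result is one non-negative "band source" per (channel, band) pair whose
fluctuations track task-locked amplitude modulation of that rhythm.

The muscle pathway rectifies the EMG, low-passes it at 4 Hz (zero phase) and
downsamples it to the same analysis rate, yielding the muscle-activity
envelopes that the regression predicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import DataError, ParameterError
from .session_io import PipelineConfig, RecordingSession


@dataclass
class BandSourceSet:
    """z-scored, smoothed band-envelope sources x_i(t).

    ``index[i]`` gives the ``(channel_name, band_name)`` of row ``i``; rows are
    ordered channel-major (all bands of channel 0, then channel 1, ...).
    Samples earlier than ``valid_from`` seconds lack a full normalisation
    window and are emitted as zero.
    """

    sources: np.ndarray  # [M x samples]
    rate: float
    index: list[tuple[str, str]]
    valid_from: float

    @property
    def n_sources(self) -> int:
        return self.sources.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sources.shape[1]

    @property
    def valid_from_sample(self) -> int:
        return int(np.ceil(self.valid_from * self.rate - 1e-9))


@dataclass
class MuscleActivitySet:
    """Non-negative muscle-activity envelopes y_k(t) at the analysis rate."""

    activity: np.ndarray  # [muscles x samples]
    rate: float
    muscle_names: list[str]


# ---------------------------------------------------------------------------
# elementary stages
# ---------------------------------------------------------------------------

def downsample(x: np.ndarray, from_rate: float, to_rate: float) -> np.ndarray:
    """Anti-aliased decimation along the last axis.

    An order-8 Butterworth low-pass at 0.8x the new Nyquist is applied (zero
    phase) before taking every q-th sample.  Non-integer but rational rate
    ratios fall back to polyphase resampling.  DC level is preserved.
    """
    if to_rate > from_rate:
        raise ParameterError(f"cannot downsample {from_rate} Hz -> {to_rate} Hz")
    x = np.asarray(x, dtype=float)
    if to_rate == from_rate:
        return x.copy()
    n_out = int(np.floor(x.shape[-1] * to_rate / from_rate))
    ratio = Fraction(to_rate / from_rate).limit_denominator(10**6)
    if (from_rate / to_rate) == int(from_rate / to_rate):
        q = int(from_rate / to_rate)
        sos = sps.butter(8, 0.8 * (to_rate / 2.0), btype="low", fs=from_rate, output="sos")
        y = sps.sosfiltfilt(sos, x, axis=-1)
        y = y[..., ::q]
    else:
        y = sps.resample_poly(x, ratio.numerator, ratio.denominator, axis=-1)
    return y[..., :n_out]


def common_average_reference(ecog: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels from every channel."""
    ecog = np.asarray(ecog, dtype=float)
    if ecog.ndim != 2 or ecog.shape[0] < 2:
        raise ParameterError("common average reference needs >= 2 channels")
    return ecog - ecog.mean(axis=0, keepdims=True)


def bandpass(x: np.ndarray, low: float, high: float, rate: float,
             order: int = 4, bidirectional: bool = True) -> np.ndarray:
    """Butterworth band-pass along the last axis.

    ``order`` is the per-skirt analogue-prototype order (the band-pass filter
    has 2*order poles).  Bidirectional application squares the magnitude
    response and cancels the phase (zero lag).
    """
    nyq = rate / 2.0
    if not (0 < low < high < nyq):
        raise ParameterError(f"band ({low}, {high}) Hz invalid for rate {rate} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    x = np.asarray(x, dtype=float)
    if bidirectional:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def causal_zscore(x: np.ndarray, rate: float, window: float = 1.0
                  ) -> tuple[np.ndarray, float]:
    """Normalise each sample by mean/SD of the trailing ``window`` seconds.

    Output at time t uses only samples strictly before t.  Samples without a
    full trailing window (t < window) are invalid and emitted as zero; the
    first valid time is returned as ``valid_from`` (seconds).  Windows with
    zero variance yield zero output with a warning.
    """
    if window <= 0:
        raise ParameterError("window must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    squeeze = x.ndim == 2 and x.shape[0] == 1
    w = int(round(window * rate))
    n = x.shape[-1]
    if n <= w:
        raise ParameterError(
            f"signal of {n} samples shorter than z-score window of {w} samples"
        )
    # trailing-window sums via cumulative sums: window for sample t is [t-w, t)
    c1 = np.cumsum(x, axis=-1, dtype=np.float64)
    c2 = np.cumsum(x * x, axis=-1, dtype=np.float64)
    s1 = c1[..., w - 1:n - 1] - np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), c1[..., :n - w - 1]], axis=-1)
    s2 = c2[..., w - 1:n - 1] - np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), c2[..., :n - w - 1]], axis=-1)
    mu = s1 / w
    var = np.maximum(s2 / w - mu * mu, 0.0)
    sd = np.sqrt(var)
    out = np.zeros_like(x)
    # variance below numerical noise of the running sums counts as zero
    degenerate = var <= 1e-12 * (s2 / w + np.finfo(float).tiny)
    if degenerate.any():
        warnings.warn("zero-variance z-score window(s); output set to 0 there",
                      RuntimeWarning, stacklevel=2)
    safe_sd = np.where(degenerate, 1.0, sd)
    out[..., w:] = np.where(degenerate, 0.0, (x[..., w:] - mu) / safe_sd)
    valid_from = w / rate
    return (out[0] if squeeze else out), valid_from


def gaussian_kernel(rate: float, width: float = 0.1, sigma: float = 0.04) -> np.ndarray:
    """Unit-sum Gaussian kernel of SD ``sigma`` truncated to total support ``width``."""
    if width <= 0 or sigma <= 0:
        raise ParameterError("width and sigma must be positive")
    radius = int(round(width / 2.0 * rate))
    k = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (k / (sigma * rate)) ** 2)
    return g / g.sum()


def envelope_smooth(x: np.ndarray, rate: float, width: float = 0.1,
                    sigma: float = 0.04, rectify: bool = True) -> np.ndarray:
    """Optionally rectify, then convolve with a zero-phase Gaussian kernel.

    Edges are handled by reflection so the output has the input length and
    constant inputs pass through with unit gain.
    """
    from scipy.ndimage import convolve1d

    x = np.asarray(x, dtype=float)
    if rectify:
        x = np.abs(x)
    kernel = gaussian_kernel(rate, width, sigma)
    return convolve1d(x, kernel, axis=-1, mode="reflect")


# ---------------------------------------------------------------------------
# composed stages
# ---------------------------------------------------------------------------

def extract_band_sources(session: RecordingSession, config: PipelineConfig,
                         dtype=np.float32) -> BandSourceSet:
    """Full cortical feature pipeline for one session.

    Stage order: downsample -> common average reference -> per-(channel, band)
    band-pass -> trailing z-score -> rectified Gaussian smoothing.  Produces
    ``n_channels * n_bands`` source rows, channel-major.
    """
    session.validate()
    config.validate()
    rate = config.target_rate
    w = int(round(config.zscore_window * rate))
    ecog = downsample(session.ecog, session.rate_ecog, rate)
    if ecog.shape[-1] <= w:
        raise ParameterError(
            "insufficient duration: session shorter than the z-score window"
        )
    ecog = common_average_reference(ecog)
    n_bands = len(config.bands)
    m = session.n_channels * n_bands
    sources = np.empty((m, ecog.shape[-1]), dtype=dtype)
    index: list[tuple[str, str]] = []
    valid_from = config.zscore_window
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate windows are flagged
        for ci, ch in enumerate(session.channel_names):
            for bi, (bname, low, high) in enumerate(config.bands):
                s = bandpass(ecog[ci], low, high, rate,
                             bidirectional=config.bidirectional_filters)
                z, valid_from = causal_zscore(s, rate, config.zscore_window)
                env = envelope_smooth(z, rate, config.gauss_width, config.gauss_sigma,
                                      rectify=config.rectify_before_smooth)
                row = ci * n_bands + bi
                sources[row] = env
                index.append((ch, bname))
    return BandSourceSet(sources=sources, rate=rate, index=index, valid_from=valid_from)


def emg_envelope(emg: np.ndarray, rate: float, config: PipelineConfig,
                 muscle_names: list[str] | None = None) -> MuscleActivitySet:
    """Rectify, low-pass (zero phase) and downsample the EMG to envelopes."""
    config.validate()
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    if not np.isfinite(emg).all():
        raise DataError("EMG contains non-finite samples")
    if rate < 2 * config.emg_cutoff:
        raise ParameterError("EMG rate below twice the envelope cut-off")
    sos = sps.butter(4, config.emg_cutoff, btype="low", fs=rate, output="sos")
    env = sps.sosfiltfilt(sos, np.abs(emg), axis=-1)
    env = downsample(env, rate, config.target_rate)
    env = np.clip(env, 0.0, None)
    if muscle_names is None:
        muscle_names = [f"muscle{i}" for i in range(env.shape[0])]
    return MuscleActivitySet(activity=env, rate=config.target_rate,
                             muscle_names=list(muscle_names))
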