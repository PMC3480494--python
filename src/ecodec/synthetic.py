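"""Synthetic recording sessions with known ground truth.

The generator emulates the statistical structure of a reach-grasp-pull task
session without any biophysical modelling:

* a trial timeline (home press, go cue, home release = trial onset, knob
  grasp, knob release, reward) with jittered reaction times and movement
  durations drawn from the subject-shaped mean +/- SD;
* per (channel, band) constant-modulus narrowband carriers (phase-normalised
  band-passed noise) whose amplitude is modulated, on task-coupled pairs, by
  smooth raised-cosine bursts locked to the movement phases;
* EMG emitted as envelope-modulated wideband interference so the EMG
  preprocessing stage is genuinely exercised; the modulating envelope is a
  known sparse linear map of lagged task envelopes and is the ground truth
  the decoder should recover.

All randomness flows from explicit seeds: the sparse ground-truth map is
drawn from ``spec.seed`` so that sessions generated with different session
seeds (e.g. a training and a hold-out session) share their true weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .session_io import (DEFAULT_BANDS, ElectrodeLayout, RecordingSession,
                         default_config)

#: movement-phase anchors: (event, offset scale) -> burst start time
#: offsets are expressed relative to trial onset / movement duration (see
#: ``_phase_times``); each coupled pair is locked to one phase.
_PHASES = ("lift", "reach", "grasp", "pull", "release", "return")

_MUSCLES_A = ["AP", "APL", "FDS", "FDP", "EDC", "FCR", "FCU", "PL", "ECU",
              "PT", "BB", "TB"]
_MUSCLES_B = ["TB", "BB", "ECR", "FCU", "EDC", "FDP", "APL", "AP"]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic subject/session family."""

    n_channels: int = 16
    grid_rows: int = 4
    grid_cols: int = 4
    n_muscles: int = 8
    n_trials: int = 248
    bands_used: tuple[str, ...] = ("delta", "gamma2")
    raw_rate: float = 2000.0
    hold_duration: float = 2.0        # s on the home button before the go cue
    reaction_mean: float = 0.2        # s, go cue -> home release
    reaction_sd: float = 0.05
    movement_duration_mean: float = 1.16  # s, onset -> knob release
    movement_duration_sd: float = 0.29
    inter_trial_interval: float = 0.8  # s of rest after the return movement
    burst_duration: float = 0.4       # s, raised-cosine support per phase burst
    burst_jitter: float = 0.05        # s, SD of burst-onset jitter
    coupling_depth: float = 1.0       # fractional amplitude modulation m
    carrier_snr: float = 20.0         # total carrier RMS / broadband-noise RMS
    emg_noise_frac: float = 0.1       # envelope noise SD / noiseless envelope SD
    pairs_per_muscle: int = 4
    muscle_names: list[str] | None = None
    subject_id: str = "synthetic-B"
    seed: int = 0

    def validate(self) -> None:
        band_names = {b[0] for b in DEFAULT_BANDS}
        unknown = set(self.bands_used) - band_names
        if unknown:
            raise ParameterError(f"bands_used outside the band list: {sorted(unknown)}")
        if self.n_channels > self.grid_rows * self.grid_cols:
            raise ParameterError("more channels than grid positions")
        if min(self.raw_rate, self.hold_duration, self.movement_duration_mean,
               self.burst_duration, self.inter_trial_interval) <= 0:
            raise ParameterError("rates and durations must be positive")
        if self.n_trials < 1 or self.n_muscles < 1 or self.pairs_per_muscle < 1:
            raise ParameterError("counts must be >= 1")
        if self.muscle_names is not None and len(self.muscle_names) != self.n_muscles:
            raise ParameterError("muscle_names length != n_muscles")
        if abs(self.raw_rate / 500.0 - round(self.raw_rate / 500.0)) > 1e-9:
            raise ParameterError("raw_rate must be an integer multiple of 500 Hz")

    def layout(self) -> ElectrodeLayout:
        loc = {_channel_name(c): (c % self.grid_cols) + 1
               for c in range(self.n_channels)}
        return ElectrodeLayout(n_rows=self.grid_rows, n_cols=self.grid_cols,
                               location_of_channel=loc)

    def channel_names(self) -> list[str]:
        return [_channel_name(c) for c in range(self.n_channels)]


def _channel_name(c: int) -> str:
    return f"ch{c + 1:02d}"


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the generative model."""

    pairs: list[tuple[str, str]]          # coupled (channel, band) pairs
    true_weights: np.ndarray              # [muscles x pairs]
    true_lags: np.ndarray                 # [muscles x pairs], seconds
    true_biases: np.ndarray               # [muscles]
    envelopes: np.ndarray                 # [pairs x samples] at envelope_rate
    envelope_rate: float
    emg_envelope: np.ndarray              # noiseless target [muscles x samples]
    events: list[tuple[float, str]]
    movement_durations: np.ndarray
    seed: int

    def support_mask(self, source_index: list[tuple[str, str]], n_lags: int,
                     lag_step: float, lag_offset: int = 0) -> np.ndarray:
        """True support in design-column space [muscles x (M*n_lags)]."""
        src_of = {tuple(s): i for i, s in enumerate(source_index)}
        K = self.true_weights.shape[0]
        mask = np.zeros((K, len(source_index) * n_lags), dtype=bool)
        for k in range(K):
            for pi, pair in enumerate(self.pairs):
                if self.true_weights[k, pi] == 0 or pair not in src_of:
                    continue
                j = int(round(self.true_lags[k, pi] / lag_step)) - lag_offset
                j = min(max(j, 0), n_lags - 1)
                mask[k, src_of[pair] * n_lags + j] = True
        return mask


def make_subject_spec(animal: str, seed: int = 0) -> SyntheticSpec:
    """Study conditions shaped like the two recorded subjects.

    Subject A: 15 channels on a 5x3 grid, 12 muscles, 134 trials, movement
    duration 3.22 +/- 0.24 s (4.0-s trial windows).  Subject B: 16 channels on
    a 4x4 grid, 8 muscles, 248 trials, movement duration 1.16 +/- 0.29 s
    (2.0-s trial windows).
    """
    if animal.upper() == "A":
        return SyntheticSpec(
            n_channels=15, grid_rows=5, grid_cols=3, n_muscles=12, n_trials=134,
            movement_duration_mean=3.22, movement_duration_sd=0.24,
            muscle_names=list(_MUSCLES_A), subject_id="synthetic-A", seed=seed,
        )
    if animal.upper() == "B":
        return SyntheticSpec(
            n_channels=16, grid_rows=4, grid_cols=4, n_muscles=8, n_trials=248,
            movement_duration_mean=1.16, movement_duration_sd=0.29,
            muscle_names=list(_MUSCLES_B), subject_id="synthetic-B", seed=seed,
        )
    raise ParameterError("animal must be 'A' or 'B'")


def trial_window_for(animal: str) -> tuple[float, float]:
    """Fixed trial windows: 4.0 s (A) and 2.0 s (B), incl. 0.5 s pre-onset."""
    return (0.5, 3.5) if animal.upper() == "A" else (0.5, 1.5)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_CARRIER_INSET = 0.15  # synthesis band inset (fraction of bandwidth) so the
                       # phase-normalised carrier keeps ~94% power in band

_LEAD_IN = 3.0  # s of rest before the first trial (> z-score warm-up + lags)
_TAIL = 2.0


def _band_edges() -> dict[str, tuple[float, float]]:
    return {name: (lo, hi) for name, lo, hi in DEFAULT_BANDS}


def _phase_times(onset: float, grasp: float, release: float) -> dict[str, float]:
    return {
        "lift": onset - 0.35,
        "reach": onset + 0.02,
        "grasp": grasp,
        "pull": grasp + 0.3 * (release - grasp),
        "release": release,
        "return": release + 0.25,
    }


def _constant_modulus_carrier(rng: np.random.Generator, n: int, rate: float,
                              lo: float, hi: float) -> np.ndarray:
    from scipy.fft import next_fast_len

    bw = hi - lo
    sos = sps.butter(4, [lo + _CARRIER_INSET * bw, hi - _CARRIER_INSET * bw],
                     btype="band", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    a = sps.hilbert(x, N=next_fast_len(n))[:n]
    return np.real(a / np.maximum(np.abs(a), 1e-12))


def generate_session(spec: SyntheticSpec, seed: int | None = None
                     ) -> tuple[RecordingSession, GroundTruth]:
    """Generate one session plus its ground truth; fully deterministic.

    ``seed`` controls the session realisation (timing, carriers, noise);
    the sparse true map (weights, lags, biases, phase assignment) is drawn
    from ``spec.seed`` only, so sessions with different seeds share it.
    """
    spec.validate()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rng_gt = np.random.default_rng(spec.seed)
    rate = spec.raw_rate
    edges = _band_edges()

    # ---- trial timeline ------------------------------------------------
    events: list[tuple[float, str]] = []
    onsets, grasps, releases, mov_durs = [], [], [], []
    t = _LEAD_IN
    for _ in range(spec.n_trials):
        home_press = t
        go = home_press + spec.hold_duration
        reaction = max(0.08, rng.normal(spec.reaction_mean, spec.reaction_sd))
        onset = go + reaction
        mov = max(0.4, rng.normal(spec.movement_duration_mean,
                                  spec.movement_duration_sd))
        grasp = onset + 0.25 * mov
        release = onset + 0.8 * mov
        events += [(home_press, "home_press"), (go, "go_cue"),
                   (onset, "home_release"), (grasp, "knob_grasp"),
                   (release, "knob_release"), (release + 0.05, "reward")]
        onsets.append(onset)
        grasps.append(grasp)
        releases.append(release)
        mov_durs.append(mov)
        t = onset + mov + spec.inter_trial_interval
    duration = t + _TAIL
    n = int(round(duration * rate))
    events.sort(key=lambda e: e[0])

    # ---- ground-truth map (from spec.seed) -----------------------------
    pairs = [(ch, band) for ch in spec.channel_names() for band in spec.bands_used]
    n_pairs = len(pairs)
    phase_of_pair = [
        _PHASES[int(i)] for i in rng_gt.integers(0, len(_PHASES), size=n_pairs)
    ]
    cfg = default_config()
    lag_grid = cfg.lag_step * np.arange(1, min(cfg.n_lags - 1, 8) + 1)  # 20..160 ms
    K = spec.n_muscles
    n_pick = min(spec.pairs_per_muscle, n_pairs)
    W = np.zeros((K, n_pairs))
    L = np.zeros((K, n_pairs))
    by_band = {b: [i for i, (_, pb) in enumerate(pairs) if pb == b]
               for b in spec.bands_used}
    for k in range(K):
        # stratified support: every muscle draws from each coupled band
        picked: list[int] = []
        for bi, b in enumerate(spec.bands_used):
            share = n_pick // len(spec.bands_used) + (
                1 if bi < n_pick % len(spec.bands_used) else 0)
            share = min(share, len(by_band[b]))
            picked += list(rng_gt.choice(by_band[b], size=share, replace=False))
        picked = np.array(picked)
        W[k, picked] = rng_gt.uniform(0.5, 1.5, size=picked.size)
        L[k, picked] = rng_gt.choice(lag_grid, size=picked.size)
    biases = rng_gt.uniform(0.1, 0.3, size=K)

    # ---- latent task envelopes (per trial, per coupled pair) -----------
    # low-frequency rhythms (< 10 Hz) carry sustained movement-spanning
    # envelopes (slow movement-related potentials); faster rhythms carry
    # short bursts locked to one movement phase
    envelopes = np.zeros((n_pairs, n), dtype=np.float32)
    sustained = {b for b, (lo, hi) in edges.items() if 0.5 * (lo + hi) < 10.0}
    for pi in range(n_pairs):
        env = envelopes[pi]
        phase = phase_of_pair[pi]
        slow = pairs[pi][1] in sustained
        for onset, grasp, release in zip(onsets, grasps, releases):
            if slow:
                t0 = onset - 0.25
                dur = (release - onset) + 0.6
            else:
                t0 = _phase_times(onset, grasp, release)[phase]
                dur = spec.burst_duration * rng.uniform(0.85, 1.15)
            t0 += rng.normal(0.0, spec.burst_jitter)
            amp = rng.uniform(0.8, 1.2)
            i0 = int(round(t0 * rate))
            i1 = int(round((t0 + dur) * rate))
            i0c, i1c = max(i0, 0), min(i1, n)
            if i1c <= i0c:
                continue
            ph = (np.arange(i0c, i1c) - i0) / max(i1 - i0, 1)
            env[i0c:i1c] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * ph))

    # ---- ECoG ----------------------------------------------------------
    n_bands_total = len(DEFAULT_BANDS)
    noise_sd = (np.sqrt(n_bands_total / 2.0) / spec.carrier_snr
                if np.isfinite(spec.carrier_snr) else 0.0)
    coupled = {pair: i for i, pair in enumerate(pairs)}
    ecog = np.empty((spec.n_channels, n))
    for ci, ch in enumerate(spec.channel_names()):
        acc = np.zeros(n)
        for band, (lo, hi) in edges.items():
            carrier = _constant_modulus_carrier(rng, n, rate, lo, hi)
            pi = coupled.get((ch, band))
            if pi is not None:
                carrier *= 1.0 + spec.coupling_depth * envelopes[pi]
            acc += carrier
        if noise_sd > 0:
            acc += noise_sd * rng.standard_normal(n)
        ecog[ci] = acc

    # ---- EMG -----------------------------------------------------------
    emg_env = np.zeros((K, n))
    for k in range(K):
        y = np.full(n, biases[k])
        for pi in np.flatnonzero(W[k]):
            shift = int(round(L[k, pi] * rate))
            y[shift:] += W[k, pi] * envelopes[pi, :n - shift]
        emg_env[k] = y
    if spec.emg_noise_frac > 0:
        sos = sps.butter(4, 4.0, btype="low", fs=rate, output="sos")
        for k in range(K):
            slow = sps.sosfiltfilt(sos, rng.standard_normal(n))
            slow *= 1.0 / max(slow.std(), 1e-12)
            emg_env[k] += spec.emg_noise_frac * emg_env[k].std() * slow
    emg_env = np.clip(emg_env, 0.0, None)
    interference = rng.standard_normal((K, n)) * np.sqrt(np.pi / 2.0)
    emg = emg_env * interference

    session = RecordingSession(
        ecog=ecog, emg=emg, rate_ecog=rate, rate_emg=rate, events=events,
        layout=spec.layout(), channel_names=spec.channel_names(),
        muscle_names=(list(spec.muscle_names) if spec.muscle_names
                      else [f"m{k + 1}" for k in range(K)]),
        subject_id=spec.subject_id,
    )
    session.validate()

    env_rate = cfg.target_rate
    step = int(round(rate / env_rate))
    gt = GroundTruth(
        pairs=pairs,
        true_weights=W,
        true_lags=L,
        true_biases=biases,
        envelopes=np.ascontiguousarray(envelopes[:, ::step]),
        envelope_rate=env_rate,
        emg_envelope=np.ascontiguousarray(emg_env[:, ::step]).astype(np.float32),
        events=events,
        movement_durations=np.array(mov_durs),
        seed=seed,
    )
    return session, gt
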