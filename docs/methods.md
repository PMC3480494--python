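# Methods

`ecodec` decodes muscle-activity envelopes from multichannel cortical-surface
(ECoG) recordings. This note documents the model and procedure, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Signal model and feature extraction

Raw ECoG (channels × samples, typically recorded at a few kHz) is

1. down-sampled to the analysis rate of 500 Hz (order-8 Butterworth
   anti-alias low-pass at 0.8× the new Nyquist, applied forward–backward,
   then decimation);
2. re-referenced to the common average across channels (CAR), so at every
   sample the channel mean is identically zero;
3. split into the seven conventional sensorimotor-rhythm bands
   δ (1.5–4 Hz), θ (4–8), α (8–14), β1 (14–20), β2 (20–30), γ1 (30–50),
   γ2 (50–90 Hz) with 4th-order Butterworth band-pass filters (the filter
   has four poles per skirt). By default filters run bidirectionally
   (zero phase, squared magnitude response); a causal single-pass mode is
   available for streaming use, where the phase delay then applies;
4. normalised by a **trailing z-score**: each band-passed sample s(t) is
   centred and scaled by the mean and SD of the preceding 1-s window
   ([t−1 s, t), strictly before t). The first second of the recording has no
   full window and is flagged invalid (emitted as zero); zero-variance
   windows also emit zero with a warning rather than NaN;
5. full-wave rectified and smoothed with a unit-sum Gaussian kernel
   (total support 0.1 s, σ = 40 ms, reflect padding, zero phase).

Step 5's rectification is a deliberate design choice: smoothing a zero-mean
oscillation with a 40-ms kernel would annihilate everything above ~10 Hz, so
"amplitude modulation" is made concrete as the rectified z-scored signal.
The literal no-rectification reading remains available via
`rectify_before_smooth=False`.

The result is one non-negative *band source* xᵢ(t) per (channel, band) pair —
M = channels × 7 sources (112 for a 16-channel grid).

EMG (muscles × samples) is rectified, low-passed at 4 Hz (4th-order
Butterworth, zero phase), down-sampled to 500 Hz and clipped at zero,
producing the muscle-activity envelopes y_k(t) that serve as regression
targets.

An important consequence of the trailing z-score is that *sustained*
amplitude changes are partially normalised away (the window statistics catch
up within ~1 s), and rectification ripple at twice the carrier frequency
survives the 40-ms kernel for the slow bands. Band sources are therefore
good but imperfect correlates of the underlying amplitude envelope — on the
4-Hz envelope bandwidth, correlations with the generative envelope saturate
around 0.75 for γ2 and 0.4–0.5 for δ even in the noise-free limit. Decoding
remains accurate because the regression pools many sources and lags.

## Decoding model

The decoder is a linear model on lagged band sources:

ŷ_k(t) = Σᵢ Σⱼ w_{k,i,j} · xᵢ(t − (j+lag_offset)·Δ) + b_k,  j = 0 … N−1,

with Δ = 20 ms and N = 10 (200 ms of history). `lag_offset` selects whether
lag j = 0 is the current sample (default, delays 0–180 ms) or strictly
causal (20–200 ms); both conventions are supported because the written
record is ambiguous about the inclusion of the current sample.

Weights are fitted per muscle by variational-Bayes sparse linear regression
with automatic relevance determination (ARD):

- Gaussian likelihood with per-muscle noise precision β ~ Gamma(10⁻⁶, 10⁻⁶);
- zero-mean Gaussian weight prior with per-column precision
  αᵢ ~ Gamma(a₀, b₀);
- coordinate updates of q(w), q(α), q(β) with a monotonically
  non-decreasing variational free energy, asserted per iteration;
- convergence when the relative free-energy change is below 10⁻⁶, at most
  500 sweeps;
- a final refresh of q(w) with the converged noise precision, so reported
  weights satisfy the stationarity condition exactly (this makes the
  frozen-α mode match the ridge closed form to machine precision, and the
  flattened-prior large-n mode match ordinary least squares).

**Sparsity calibration.** The α-hyperprior shape a₀ is the sparsity knob.
At the variational fixed point a column survives only if its squared
standardised correlation z² with the residual satisfies
(z²−1)²/(4z²) ≥ 2a₀; with near-flat hyperpriors (a₀ → 0) every column with
|z| > 1 survives — about a third of pure-noise columns — and the precisions
of dead columns grow only linearly per sweep, so no finite threshold is ever
crossed. The default a₀ = 2 (rate b₀ = 10⁻¹²) retains coefficients above
roughly four standard errors, makes dead-column precisions diverge
geometrically (×(1+2a₀) per sweep), and empirically yields exact support
recovery on sparse ground truth and zero active columns on pure-noise
targets. Columns whose precision exceeds the absolute `prune_threshold`
(10⁸; appropriate for the unit-scale features the z-scoring guarantees) are
removed from the active set and their weights are exactly zero. Pruning is
taken as the analytic limit of the diverging trajectory; the recorded free
energy is shifted by the (constant) contribution of the removed columns at
prune events so the trace stays comparable and monotone across the fit.
Fits are deterministic — there is no randomness anywhere in the algorithm.

All updates consume only the sufficient statistics XᵀX, Xᵀy, yᵀy and n,
accumulated in fixed-size row chunks from a lazily materialised design
matrix, so multi-hundred-second sessions never require the dense
[rows × M·N] matrix in memory, and refitting from an identical row set is
bit-for-bit reproducible.

## Evaluation

Accuracy is assessed by trial-wise k-fold cross-validation (default k = 10).
Trials are fixed windows around movement onset (the home-button release
event); the fold split is a seeded random partition with fold sizes
differing by at most one. Each fold fits on the rows of the training-subset
trials — by default every 5th row in the shipped analyses (the envelopes are
band-limited to 4 Hz, so a 100-Hz fitting grid loses nothing; predictions
and metrics always use the full 500-Hz resolution) — and is scored on the
held-out trials. Metrics per trial and muscle:

- CC: Pearson correlation between actual and predicted envelopes (negative
  values are retained in all numeric reports);
- nRMSE: RMS error divided by the range (max − min) of the *actual* trace,
  computed per trial in trial-wise mode and over the whole span in
  continuous mode.

Summaries: per (fold, muscle) mean ± SD over trials; per muscle the grand
mean (mean of fold means) ± SEM (SD of fold means / √k, SD with one degree
of freedom removed). The default protocol uses k−1 training subsets per
fold; `train_subsets_per_fold` can reproduce reduced-training variants.

Continuous evaluation performs one uninterrupted prediction pass over a
stated span (no trial segmentation) and refuses spans that overlap the
model's training data (leakage guard keyed on session identity and time).

**Controls.** Two negative controls are provided and they measure different
things. `random_segment_control` refills every trial window with EMG drawn
from a uniformly random task phase; refitting on these targets measures
chance-level decoding (CC ≈ 0). `permute_trial_blocks` swaps onset-aligned
trial contents between trials; because both features and targets remain
time-locked to the onset in a stereotyped task, a decoder can still predict
the across-trial template, so this control estimates the *stereotypy
ceiling* (CC ≈ 0.79 at full scale, versus ≈ 0.88 for the true decode) — not
chance. Treating trial permutation as a chance-level null is a common
misconception that these two controls make explicit.

## Weight-contribution analysis

For each fold and muscle, |w| is averaged over the lag axis, channels are
averaged within their electrode-grid column ("location"; column #1 is the
most caudal, nearest the central sulcus), and the (band × location) cells
are divided by the per-muscle maximum, so each (fold, muscle) sheet has
maximum exactly 1. The summary per (band, location) is the median over
muscles within a fold, then the mean of those medians across folds.
Absolute values are taken before lag-averaging because signed averaging
would cancel oscillatory-phase weights; a signed mode is available. The
long-format export (fold, muscle, band, location, value) is the input a
3-way ANOVA would consume; the ANOVA itself is out of scope.

## Synthetic sessions

The generator produces complete raw sessions with known ground truth:

- **Timeline** — home press, 2-s hold, go cue, reaction (0.2 ± 0.05 s),
  home release (= trial onset), knob grasp, knob release, reward; movement
  duration drawn per trial from the subject-shaped mean ± SD (3.22 ± 0.24 s
  and 1.16 ± 0.29 s for the A- and B-shaped specs), plus a 0.8-s rest.
- **Cortical carriers** — per (channel, band) constant-modulus narrowband
  carriers: band-passed white noise (synthesis band inset 15% of the
  bandwidth) normalised by its Hilbert envelope. Each carrier keeps ≥ 90% of
  its power inside the nominal band edges while carrying no amplitude
  fluctuation of its own, so imposed task modulation is the only envelope
  signal.
- **Task coupling** — every channel of the task-coupled bands (default δ
  and γ2) is modulated as carrier × (1 + m·e(t)) with coupling depth m = 1.
  Latent envelopes e(t) are raised-cosine bursts: γ-band pairs get short
  bursts (0.4 s ± jitter) locked to one of six movement phases; low-band
  (< 10 Hz centre) pairs get sustained movement-spanning envelopes,
  mirroring slow movement-related potentials. Broadband white noise is
  added at a total carrier-to-noise ratio of 20.
- **EMG** — each muscle's envelope is a sparse positive linear map (four
  (channel, band) pairs per muscle, stratified across the coupled bands,
  weights U(0.5, 1.5), lags on the 20-ms grid up to 160 ms) of the latent
  envelopes, plus a tonic baseline and 10% band-limited envelope noise; the
  emitted raw EMG is that envelope multiplied by wideband Gaussian
  interference scaled to unit mean absolute value, so the EMG preprocessing
  stage is genuinely exercised.
- **Seeding** — the sparse true map is drawn from `spec.seed` while the
  session realisation uses the `generate_session` seed, so a training and a
  hold-out session share their ground-truth weights. Everything is
  deterministic given the two seeds; there is no global random state.
- **Raw rate** — sessions are synthesised at 2 kHz (an integer multiple of
  the 500-Hz analysis rate) so the downsampling stage runs at a realistic
  4:1 ratio while keeping a 17-minute session comfortably in memory.

What the generator does **not** emulate: biophysical cortical or
musculoskeletal dynamics, grip-force signals, electrode artifacts, line
noise, cross-channel correlated noise, non-stationary carrier spectra, or
negative (inhibitory) weight structure. Passing tests therefore demonstrate
that the pipeline recovers the stated class of band-envelope codes under
realistic timing and noise — not that real recordings will reach the same
accuracy.

## Problem sizes in the shipped analyses

The end-to-end checks use the full B-shaped study (248 trials, 16 channels,
8 muscles, ≈ 17-minute session; 1120 design columns; ≈ 45 000 fitting rows
per fold at the 100-Hz fitting grid), which cross-validates in a few minutes
on one core. Unit tests use a 30-trial session with identical geometry. The
sparse-recovery checks use n = 2000 rows × 500 columns with 10 true nonzero
weights and 5% noise.

## Known limitations

- The trailing z-score makes band sources ratio-like (relative to the
  preceding second); decoders trained on them transfer across sessions only
  to the extent that the rest-level statistics match.
- Per-scalar ARD is implemented; grouped (per-channel or per-pair) relevance
  is not, so "pruning channels" in the strict sense emerges only when all of
  a channel's columns die individually.
- The k-fold splitter partitions trials, not time: adjacent trials can land
  in different folds, which is faithful to the original protocol but
  optimistic if slow drifts correlate neighbouring trials.
- `nrmse` is undefined (NaN) for flat actual traces; callers must tolerate
  NaNs for muscles that are silent within a window.
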