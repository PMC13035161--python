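# Methods

This package implements, end to end, a nocturnal photoplethysmography
(PPG) analysis for paired recordings from a clinical-grade fingertip
pulse oximeter (transmission mode, 256 Hz) and a consumer smart ring
(50 Hz) worn simultaneously during sleep. Because no public recordings
of this kind exist, the package ships a synthetic-data generator that
defines the study conditions; every downstream stage — pulse
extraction, fiducial features, device agreement, vascular-age models —
is tested against the generator's analytic ground truth.

## Synthetic cohort and signal model

**Demographics.** Ages are drawn from three bins (20–39, 40–59, 60–70
years with probabilities 0.68 / 0.21 / 0.11, uniform within bins),
matching a right-skewed wearable-user population with median ≈ 31–35
years; sex is Bernoulli(0.49 male); BMI ~ N(23, 3²) truncated below
35 kg/m²; office SBP and DBP carry mild positive age slopes
(0.35 and 0.15 mmHg/year) around 100/70 mmHg at age 35 with residual
SDs of 12/8 mmHg.

**Beat model.** Each beat of duration *d* is a closed-form waveform on
x ∈ [0, 1):

    w(x) = a1·exp(−(x−μ1)²/2σ1²) + a2·exp(−(x−μ2)²/2σ2²)
           + ramp·(1−x)·foot(x) + c·x·(1−x)

The two Gaussians are the systolic and reflected diastolic waves. The
`ramp` run-off (0.08) with a short foot rise (`foot` saturates over the
first 6 % of the beat) gives every beat a sharp foot exactly at the
beat boundary, and the small x(1−x) term (c = 0.16) keeps the waveform
rising monotonically from the foot into the systolic upstroke even when
the systolic peak is late, while steepening the diastolic tail into the
next foot, as in real pulses. All landmarks of w are recoverable by
dense grid search (`implied_features`), which serves as the ground
truth for the whole pipeline.

**Age trends and device offsets.** On the 200-sample normalized-pulse
grid, crest time (CT) rises 0.30 samples/year from 33 at age 20, the
systolic–diastolic interval (dT) falls 0.35 samples/year from 65.5, and
the reflection index (RI) rises 0.005/year from 0.45. Around each trend
every participant carries a latent deviation (SD 5.5 / 7.7 / 0.104),
derived from a stable hash of the participant id so both devices share
it. The ring adds +6 samples to CT and +0.23 to RI, has a rounder
systolic peak (σ1 0.065 vs 0.045), an RI–age slope attenuated to 0.4 of
the fingertip's, and log-normal contact-pressure jitter (SD 0.10) on
the reflected-wave amplitude. These values are calibrated so an N = 160
cohort reproduces feature–age correlations near CT ≈ 0.64, dT ≈ −0.51,
RI ≈ 0.58 (fingertip) / 0.22 (ring) and device biases near +6 samples
(CT) and +0.2 (RI); the amplitude a2 is solved by bisection so the
*implied* RI of the full mixture (not a2 itself) hits its target.

**Nights.** Beat durations are N(60/HR, 0.03²) seconds (participant HR
~ N(62, 6²) bpm), shared exactly between the two devices (simultaneous
recording). Baseline drift is a 0.02 Hz sinusoid of amplitude 1.5
systolic units (below the analysis passband); white noise SDs are
0.02 / 0.04 (fingertip / ring); optional motion artifacts are 1–5 s
sinusoidal excursions at 0.5–2 Hz with ~8× systolic amplitude, injected
at a configurable Poisson rate. Default night length is 330 s at desk
scale (the real study records whole nights; nothing in the pipeline
depends on the night length beyond pulse counts).

Blood pressure in the generator depends on age (and noise) only — there
is no latent vascular-aging factor linking BP to pulse morphology beyond
age. Age-adjusted ΔAge is therefore unrelated to BP by construction, and
the ΔAge-tertile BP contrasts are expected to be null on synthetic
cohorts; the tertile machinery is validated by construction-based and
type-I-error simulations instead.

**Nonlinear option.** With `age_map="saturating"` the effective age
driving all trends is warped through 20 + 50·((age−20)/50)², and the
latent deviations shrink by 0.5: a cohort whose morphology tracks age
closely but nonlinearly, used to compare the model families.

**What the generator does not emulate.** Sleep-stage-dependent
morphology, SpO₂, real sensor nonlinearities, heart-rate drift across
the night, and waveform shapes beyond the two-Gaussian family. Tests
passing on this generator show the pipeline is internally consistent
and recovers known structure; they do not certify performance on real
recordings.

## Pulse extraction

- **Filter:** 0.05–20 Hz 4th-order Chebyshev type II (30 dB stopband),
  applied forward–backward for zero phase after mean removal; type II
  keeps the passband flat so feature timing is preserved. Requires
  fs > 40 Hz.
- **Artifact mask:** moving 2-s peak-to-peak envelope; samples above
  3× the median envelope are masked, padded 1 s each side. 30-s windows
  with > 20 % masked samples are flagged and skipped.
- **Windows:** non-overlapping 30 s tiles of [lights_off, lights_on),
  trailing partial window dropped; 0-based half-open sample intervals
  throughout.
- **Onsets:** slope-sum transform (128 ms trailing window of positive
  differences); candidate peaks ≥ 0.25 s apart are accepted greedily by
  height under a refractory of 0.55× the dominant beat period (lag of
  the slope-sum autocorrelation maximum in 0.4–2 s). Height thresholds
  alone cannot reject the secondary upstroke of a large reflected wave
  (its slope-sum peak reaches ~0.7 of the systolic one on ring
  signals); the refractory rule can. Each onset is the signal minimum
  in the 0.3 s before its slope-sum peak, shifted +20 ms because the
  zero-phase band-pass anticipates each upstroke by about half its
  step-response rise time, which would otherwise bias every foot early
  by that amount. Onsets whose search window is clipped by the window
  start are dropped (partial beat).
- **Plausibility:** onset-to-onset intervals kept iff within 0.4–2 s
  and within 40 % of the previously retained interval; after two
  consecutive bounds-passing intervals that fail only the 40 % rule the
  reference is considered stale and the next interval re-anchors it
  (a single aberrant anchor would otherwise reject an entire healthy
  window).
- **Baseline:** cubic spline through the (onset, value) knots,
  subtracted; windows with < 4 plausible onsets are skipped.
- **Normalization:** each beat is cubic-spline resampled to 200 samples
  and min-max scaled to [0, 1]; the source duration is kept so CT/dT
  can be expressed in seconds.
- **Quality check:** a pulse is accepted iff its Pearson correlation
  with the window's mean pulse is ≥ 0.90 (configurable). The real
  study names a quality check without parameters; this criterion and
  threshold are this package's choice.

## Fiducial points and features

Per window, the template (pointwise mean of accepted pulses) is fitted
with two Gaussians by bounded nonlinear least squares (second center
parameterized as a positive offset from the first, centers within
[1, 198]). Derivatives of each pulse are taken from one
Savitzky–Golay smooth (window 9, order 3) for all orders, so
3rd-derivative zero crossings stay well defined under noise, and the
detector is invariant to amplitude scaling. Fiducials:

- onset = sample 0, offset = 199;
- systolic peak = first positive-to-negative 1st-derivative zero
  crossing whose amplitude is at least half the pulse range (the
  dominance guard skips derivative wiggles near the foot that cannot be
  the systolic peak);
- estimated diastolic peak = 1.10 × fitted second-Gaussian center
  (10 % of its distance from the onset, which sits at index 0);
- dicrotic notch = positive-to-negative 3rd-derivative crossing in the
  systolic–estimated-diastolic segment nearest the estimate;
- diastolic peak = first positive-to-negative 1st-derivative crossing
  between notch and estimate; if none exists (reflected wave merged
  with the direct wave) the estimate itself is used and flagged.

Zero crossings are located with linear sub-sample interpolation and
rounded to the nearest sample, ties toward the earlier sample. Features
are CT = systolic − onset, dT = diastolic − systolic (200-grid samples,
seconds variants scaled by duration/200) and RI = diastolic/systolic
amplitude ratio. Window features are componentwise medians
(mean-of-middle for even counts). Templates are fitted per 30-s window,
the unit of feature aggregation.

Participant-level pairing follows the study design: windows paired
across devices at the window level, participants with < 20 valid pairs
excluded, 20 pairs sampled with a seeded generator, features averaged
over the sample. On a 50 Hz device one raw sample spans ~5 samples of
the 200-grid, so ring-side agreement with ground truth is
quantization-limited at about one raw sample; tests check the fingertip
at 2 grid samples and the ring at the quantization bound.

## Age models

**Feature regression:** ordinary least squares of age on (CT, dT, RI),
fitted per fold; rank-deficient designs fall back to the minimum-norm
solution with a logged warning.

**CNN:** a compact 1D network — two stride-1 conv layers with no
pooling, ReLU throughout, two fully connected layers with dropout 0.2
after each, and one linear output. The reference configuration is 16
filters (kernel 11) then 32 filters (kernel 9) with 1024-unit FC
layers; its conv stack sees 19 samples (~9.5 % of the pulse). The
network, its backward pass, and the optimizers are implemented in
numpy (im2col convolutions, hand-derived gradients), which keeps
training bit-reproducible given a seed. Adam (β₁ = 0.9, β₂ = 0.999) and
momentum SGD (momentum 0.9; the β terms are adaptive-optimizer
parameters, so for SGD β₁ is applied as momentum) share a weight decay
of 1e-7 applied through the gradients. Loss is mean squared error;
mean absolute error is the reported metric. Desk-scale experiments use
a narrower preset of the same depth and kernels (`CNNConfig.small()`),
since the 1024-unit reference head is sized for GPU-scale training.

**Cross-validation:** folds are built at the participant level (k = 10
by default); within each fold the non-test participants are shuffled
and split 8:1 into training and validation (128/16/16 at N = 160).
Disjointness is asserted inside the pipeline, not only in tests. Pulse
counts are standardized by sampling n pulses per participant and device
(370 in the study design; participants under the threshold on either
device are excluded). A heuristic grid (learning rate {1e-3, 1e-4} ×
batch {128, 256} × {adam, sgd} by default) is searched per fold on
validation MAE with early stopping (patience 10, max 100 epochs;
desk-scale runs use ≤ 30 epochs) and best-epoch weight restoration.
Participant predictions are the median over pulse-level outputs.

**Grad-CAM:** per pulse, the gradient of the scalar output with respect
to the last conv layer's activations is averaged over time per channel;
the rectified channel-weighted activation sum is linearly resampled to
200 samples and max-normalized; group maps (age bins 20–39, 40–59, ≥60)
are means of pulse maps, max-normalized again.

## Statistics

- Metrics: MAE, RMSE, R² = 1 − SSE/SST, Pearson r (reported missing
  for constant vectors).
- Corrected resampled t-test: paired per-fold differences with variance
  inflated by (1/k + n_test/n_train), two-sided p on k−1 df; Bonferroni
  across the four-metric panel when run as a panel. Strictly more
  conservative than the uncorrected paired test whenever
  n_test/n_train > 0.
- Fisher z comparison of correlations in its independent-samples form
  (the device correlations are in fact paired; the dependent-correlation
  variant is not used, matching the named test).
- Bland–Altman: bias mean ± 1.96 × sample SD (n−1 divisor);
  proportional-bias slope from regressing differences on pair means or
  on chronological age, with 95 % CI.
- ΔAge: raw ΔAge = predicted − chronological age; age-adjusted ΔAge =
  OLS residuals of raw ΔAge on age (exactly orthogonal to age by
  construction).
- Tertiles: cut at the empirical 33.3/66.7 percentiles by stable-sorted
  rank; BP ~ tertile + age + sex + BMI with sex as a binary indicator;
  adjusted means at covariate sample means; pairwise contrasts
  Bonferroni-corrected (×3). A constant outcome short-circuits to zero
  contrasts with p = 1 (numerically the OLS t-ratios of a constant fit
  are 0/0 noise).
- Waveform similarity: maximum Pearson correlation of the two mean
  pulses over integer lags within ±20 samples.

## Problem sizes and reproducibility

Desk-scale experiments use N = 160 participants with 100 pulses per
participant for the model studies (10-fold CV, one grid point, ≤ 30
epochs for the CNN) and N = 60 participants with ~23 paired 30-s
windows for the full signal-chain feature and agreement analyses.
All randomness flows from named integer seeds through
`numpy.random.default_rng`; identical (config, seed) pairs give
bit-identical cohorts, fold assignments, and trained networks.
`scripts/acceptance.py` re-runs both studies from scratch and writes
the headline numbers as JSON.

## Known limitations

- The generator's beat family is two-Gaussian; real dicrotic notches
  vary more, and fiducial behaviour on pathological waveforms is
  untested.
- Ring-side CT agreement with ground truth is limited by the 50 Hz
  sampling grid (~20 ms per sample, ≈5 samples of the 200-grid), so
  extracted device biases in CT run higher than the generator's
  configured offset.
- Under heavy noise the merged-wave fallback places the diastolic peak
  at the template estimate (10 % beyond the fitted second-Gaussian
  center), which can bias window dT late on the noisier device; and
  min–max amplitude normalization under additive noise inflates the
  pulse range, slightly diluting RI — more so at higher noise levels,
  which narrows the measured ring–fingertip RI offset relative to the
  generator's configured value.
- The corrected resampled t-test's reference per-fold values from the
  original study are not available, so it is validated against its
  closed form rather than published p-values.
- Fisher's z is applied in independent-samples form to paired device
  correlations (anticonservative for positive dependence).
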