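# Methods

somnoscope implements the decision-support core of an explainable sleep
stager: a template-guided convolutional network whose internal components —
refined clinical filters, their activation traces, and input-gradient
saliency — are turned into four stage-routed explanation products, plus the
evaluation statistics used to compare human scoring settings.  This note
records the model, the choices made where the design was open, and what the
synthetic data do and do not establish.

## Synthetic sleep EEG

Real overnight polysomnography is replaced by a seeded generator that emits
single-channel EEG (µV) in 30-second epochs, one AASM stage per epoch.

**Hypnograms** are first-order Markov chains over (W, N1, N2, N3, REM).  The
default transition matrix favors stage persistence, the W→N1→N2→N3 descent
and N2→REM transitions; it is a plausibility choice, not a fit to data.

**Epoch recipes.**  Each stage mixes continuous rhythms (random-phase
sinusoids) and transient events built from the same canonical morphologies
as the template filters, plus white Gaussian noise (default SD 5 µV):

| stage | background | events (annotated) |
|---|---|---|
| W   | alpha 10 Hz, 30 µV | — |
| N1  | alpha ×0.4 + theta 6.5 Hz, 15 µV | 0–1 vertex sharp waves (60 µV, 0.3 s) |
| N2  | theta | ≥1 spindle (13 Hz burst, 25 µV, 1 s) and/or k-complex (biphasic, 80 µV, 1 s) |
| N3  | faint theta (×0.3) | delta waves (1.5 Hz, 75 µV, 1 s) tiling `delta_coverage` (default 0.35) of the epoch |
| REM | theta | 1–2 sawtooth trains (3 Hz triangular, 40 µV, 1.5 s) |

Frequency bands follow AASM convention: delta 0.5–4, theta 4–8, alpha 8–13,
spindles 11–16 Hz.  Amplitudes are free parameters (the clinical literature
reports ranges, not single values); defaults follow typical adult scalp EEG
scales and the ≥75 µV slow-wave criterion.  The optional sweat artifact is a
0.3 Hz, 120 µV baseline sway — deliberately inside the delta filter's
passband, reproducing the known confusion between sweat artifacts and slow
waves.

Because planted events share their morphology with the template kernels,
each template acts as a matched filter for its own event type.  This makes
the task *learnable by construction* (a naive-Bayes oracle on band powers
exceeds 95% accuracy) and is the main idealization: real EEG events vary in
shape, frequency and amplitude, overlap each other, and sit on colored
(1/f) background.  Passing tests therefore establish that the machinery is
correct and well-calibrated on signals with the assumed statistical
structure, not that the stager or the detectors reach clinical performance
on real recordings.

Annotation soundness is checked by band-pass energy: at zero noise, ≥90% of
an epoch's energy inside an event type's characteristic band must fall
within the union of that type's annotated intervals (FFT brick-wall
band-pass; intervals dilated by 0.25 s to absorb the band-limited spread of
short transients).

## Template filters and refinement

Seven unit-norm canonical kernels (default 1 s at 100 Hz) cover alpha,
theta, delta, sawtooth, vertex sharp, spindle and k-complex morphologies.
Refinement keeps only clinically meaningful content:

* **delta** — low-pass at 4 Hz (delta activity is defined below 4 Hz);
* **spindle** — samples outside the burst support are zeroed;
* **k-complex** — support selection first, then low-pass at 4 Hz;
* the other four patterns pass through unchanged.

The low-pass is a zero-phase FFT-domain brick-wall mask (bins at or above
the cutoff are zeroed).  A soft roll-off was considered and rejected: any
mask with values strictly between 0 and 1 is not idempotent, and refinement
is specified as a projection (applying it twice must be a no-op).  The
brick-wall mask is exactly idempotent, never increases kernel energy, and
leaves zero power above the cutoff; ringing is immaterial for 100-sample
kernels.  Kernels are *not* re-normalized after refinement — detection
thresholds are calibrated downstream instead, so refinement stays a pure
projection.

## The stager

The smallest architecture exposing all three explanation sources:

    conv1d (7 frozen template filters + 8 free filters, kernel 100,
    stride 1, zero-padded "same")
    → ReLU → temporal mean-pooling (100-sample bins)
    → dense(32, ReLU) → dense(5) → softmax

Inputs are per-epoch standardized.  Training uses cross-entropy, Adam
(lr 1e-3), class-balanced sampling, and early selection of the checkpoint
with the best validation macro-F1.  Template filters are frozen by default
so the refined kernels remain clinically interpretable after training (a
config flag allows fine-tuning).  The network is implemented directly in
numpy: the convolution runs in the FFT domain, and all gradients — for
Adam and for saliency — are analytic.  Correctness is enforced by oracles
rather than trust: activation traces must match a direct sliding
dot-product to 1e-6, and saliency must match central finite differences to
1e-3 relative (probes that cross a rectifier kink are excluded, since a
two-sided difference there averages two distinct slopes).  Training is
bit-reproducible for a fixed seed on a fixed thread count.

Explanation sources:

* **activation traces** are the *pre-nonlinearity* convolution of one
  template filter with the epoch, mapped 1:1 to input samples; they are
  computed on the signal as given (no standardization), so the trace is
  linear in the input up to the bias term;
* **saliency** is the absolute vanilla gradient of the target stage's
  pre-softmax score with respect to the standardized input; smoothed or
  integrated variants are out of scope.

## Explanation products and routing

Template activations oscillate at their pattern's frequency, so detection
operates on the analytic (Hilbert) envelope of the trace — the "amplitude
of the activation" — rather than on signed values; otherwise every event
would fragment into half-cycle runs.

1. **Detection boxes**: maximal envelope runs strictly above a per-pattern
   threshold, runs separated by ≤0.1 s merged, runs shorter than the
   pattern minimum (spindle/k-complex 0.3 s, delta 0.25 s) dropped.  These
   minima are shorter than any canonical event and configurable.
2. **Delta blocks**: the delta envelope digitized at a threshold (strictly
   "higher than" encodes 1), short gaps closed; maximal runs of 1 are the
   blocks a scorer counts.  The N3 rule fires when digitized coverage
   strictly exceeds 20% — computed on the digitized activation, i.e. on
   what the scorer perceives, not on generator annotations.
3. **Alpha surface**: the rectified alpha activation, unsmoothed; its area
   tracks alpha amplitude, which separates W from N1.
4. **Saliency highlights**: maximal runs strictly above a per-epoch
   percentile (default 90th).  The percentile is per-epoch, not global,
   because the display always shows one epoch; constant saliency yields no
   highlights by the strict inequality.

Only the products mandated for the predicted stage enter the bundle
(W/N1: alpha + highlights; N2: boxes + alpha + highlights; N3: delta +
highlights; REM: boxes + alpha + highlights).  N2 boxes come from the
spindle and k-complex filters; REM boxes from the sawtooth filter only —
spindles/k-complexes indicate N2, so showing them under a REM prediction
would argue against the model's own output.

**Threshold calibration** maximizes event-level F1 (greedy one-to-one
matching at IoU ≥ 0.3) of `detect_boxes` against planted events over a
24-point grid from the median to the maximum of the pooled envelope;
ties keep the lowest threshold.  Patterns with no calibration events fall
back to the 95% envelope quantile with a warning.  Calibration is fully
deterministic.  With sweat artifacts enabled, delta thresholds calibrated
on clean data mark essentially the whole of an artifact-contaminated wake
epoch as delta (the test suite reports the false coverage); this failure
mode is inherited by design, not corrected.

## Evaluation statistics

* **macro-F1** averages per-class F1 over the classes present in the truth
  sequence only; 15-minute segments rarely contain all five stages, and
  averaging over absent classes would deflate scores arbitrarily.
* **Cohen κ** is the unweighted chance-corrected agreement; the degenerate
  case p_o = p_e = 1 (both raters constant and identical) is defined as 1.
  Pairwise κ enumerates every unordered rater pair per shared segment.
* **Correction rates** over AI-incorrect epochs report the fraction revised
  and the fraction revised to the true stage.  The conditional reading
  ("among detected errors") is also reported; the unconditional
  all-incorrect denominator is the default because it is well-defined even
  when no epoch is revised.

### Clustered Wilcoxon signed-rank test

Paired scores contributed by the same rater are correlated, so the plain
signed-rank variance understates the truth.  The test statistic is the
total signed rank T = Σ s_ij R_ij (zero differences dropped, midranks for
ties).  Its null variance is estimated as

    Var(T) = Σ R² + Σ_c ρ̂₋c · [(Σ_j R_cj)² − Σ_j R²_cj]

where ρ̂₋c = 2π̂₋c − 1 and π̂₋c is the within-cluster sign-concordance
fraction pooled over the *other* clusters.  The leave-one-cluster-out
estimate decouples a cluster's score from its own variance weight, which
keeps the normal-approximation test close to nominal size with as few as
4 clusters (simulated two-sided size ≈ 0.04 at α = 0.05 for 4 clusters of
10 i.i.d. pairs; the alternative of using squared cluster sums directly
bounds |z| by √C and collapses to a size of ~0.003 there).  With singleton
clusters the cross terms vanish and the test reduces *exactly* to the
normal-approximation Wilcoxon signed-rank test with tie correction, which
is the oracle used in the tests.  Known limitations: with very few, highly
correlated clusters the moment estimate is noisy and the test can exceed
nominal size; the normal approximation is used throughout (no exact
enumeration); p-values are one-sided "greater" by default because the
study design tests for improvement.  Effect size is r = z/√n.

The signed-rank statistic is exactly invariant under increasing *affine*
transforms applied to both members of every pair (ranks of |d| are
preserved); general monotone maps change the ranks, so invariance is
tested for the affine class.

## Problem sizes and numerics

Defaults keep everything desk-scale: fs = 100 Hz (resolves the spindle
band with Nyquist margin), 3,000-sample epochs, 500/100 train/validation
epochs for the learnability checks, 200/100 calibration/held-out epochs
for detection, 2,000 replicates for the type-I simulation, 10,000 epochs
for the Markov frequency check.  The pipeline's default run simulates 20
recordings × 60 epochs and splits them 80/10/10 by recording.  All
randomness flows from a single seed through `numpy.random.SeedSequence`;
floating point is float64 throughout.  Strict inequalities are used at
every threshold (ties encode 0 / unhighlighted / not-N3).

## Known limitations

* Single-channel EEG only; no EOG/EMG/ECG, so REM identification leans
  entirely on sawtooth waves.
* The generator's matched-morphology events make detection easier than on
  real data; reported F1 values are upper bounds on realistic behavior.
* One conv layer cannot express multi-epoch temporal context; whole-night
  architecture effects are out of scope.
* The clustered test's small-cluster behavior is approximate (see above).
* Rendering is a static SVG with a layer manifest; no interactive review
  interface.
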