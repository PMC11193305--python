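# Methods

This note documents the models, parameter choices, and numerical
conventions of `lvepulse`, and what the synthetic experiments do and do
not establish.

## Synthetic cohort model

The generator emulates a two-group heart-failure cohort observed through
upper-arm pulse recordings and echocardiography.

**Waveforms.** Each subject's cycle template is a 3rd-order Fourier sum.
Per order n ∈ {1,2,3} a harmonic power Cₙ is drawn from the group's normal
distribution (defaults, mean ± SD: non-LVE 3.11 ± 0.65, 0.61 ± 0.21,
0.13 ± 0.10; LVE 2.92 ± 0.74, 0.69 ± 0.35, 0.12 ± 0.09; truncated below
at 0.01 so powers stay positive), a phase φₙ ~ Uniform[0, 2π) is drawn,
and the coefficients are Aₙ = Cₙ cos φₙ, Bₙ = Cₙ sin φₙ. Power is
phase-invariant, so the drawn Cₙ is exact ground truth for the analysis
round-trip, while phase randomness produces realistic morphological
diversity. The offset A₀ is set so the template minimum is slightly above
zero (pressure-like nonnegativity); each cycle is rotated to start at its
minimum, because downstream segmentation is foot-to-foot.

**Recordings.** Defaults: 8 cycles per subject of nominally 125 samples at
125 Hz (≈ 1 s cycles, a plausible resting heart rate), per-cycle length
jitter ±5 %, additive Gaussian noise with SD 0.35 (≈ 5 % of a typical
peak-to-peak amplitude of ~7 units), and one slow sinusoidal baseline
wander of amplitude 0.5 with period ≈ 10 cycles (the simplest
respiratory-like drift that exercises denoising). Ground-truth cycle
boundaries and harmonic powers are stored on each recording.

**Anthropometrics and LVDdI.** Sex (55 % male), height and weight follow
generic adult normals; BSA uses Du Bois. LVDdI is drawn per group and sex
(defaults: non-LVE 30/31 ± 3, LVE 42/43 ± 4 mm/m² for males/females),
truncated at the sex-specific threshold so group membership and the
threshold label always agree; LVDd is back-computed as LVDdI × BSA rather
than inventing a joint anthropometric–cardiac model. Incomplete records
are modeled as a missing echocardiographic LVDd; the incomplete count is
`round(total × fraction)` allocated to groups by largest remainder, so
complete-group sizes are deterministic. The packaged screening-flow
fixture (fixed seed) generates 264 subjects of whom 37 are incomplete and
the remaining 227 split 137 non-LVE / 90 LVE.

**Deterministic-LVDdI mode.** For identifiability experiments the
stochastic LVDdI draw can be replaced by a fixed linear map of the true
powers, LVDdI = 5 + 8·C₁ + 10·C₂ (mean ≈ 36, SD ≈ 5.6 mm/m² under the
default power distributions — enough spread that predicting the cohort
mean is clearly insufficient). In this mode group labels are not
clinically meaningful; the mode exists to test whether the regressor can
recover a known waveform→LVDdI relationship.

**What the generator does not emulate.** Hemodynamic realism (Windkessel
or transmission-line wave shapes, reflected waves), device-specific noise
spectra, arrhythmic or ectopic beats, and any real covariance between
waveform morphology and ventricular size beyond group membership. Tests
passing on this cohort therefore demonstrate the *correctness and
statistical behavior of the pipeline*, not clinical performance;
reproducing the clinical headline metrics is out of scope by design since
the clinical recordings are unavailable.

## Preprocessing

Wavelet denoising uses Daubechies-4 at level 4 with soft universal
thresholding (threshold σ√(2 ln n), σ from the MAD of the finest detail
coefficients); these are conventional biosignal defaults, all
configurable. Cycle feet are prominent local minima of a Savitzky–Golay
smoothed copy (window 0.05 s, order 2), at least 0.4 s apart with
prominence ≥ 25 % of the signal range; foot-to-foot is standard for arm
pulse waves. On noise-free generated recordings detected boundaries match
the ground truth within ±2 samples.

Each cycle is linearly resampled to exactly 100 points over the periodic
phase axis [0, 1) — the right endpoint is excluded because it equals the
next foot — which preserves the one-period Fourier convention used
downstream (a 3rd-order refit of a resampled 137-point cycle matches the
source coefficients to ≲ 1e−3, limited only by linear-interpolation
error). Amplitude is then mapped affinely to [0, 100]; a constant cycle
has no defined normalization and is flagged invalid. Each normalized
cycle retains its pre-normalization extrema, so the affine map is exactly
invertible: harmonic powers meant to be compared across subjects are
computed on the restored physical amplitude scale, since the 0–100
normalization would otherwise rescale them per cycle.

A subject is valid when ≥ 5 valid cycles survive.

## Harmonic analysis

The Fourier fit is ordinary least squares of the 7-parameter basis {1,
cos kωt, sin kωt}ₖ₌₁..₃ on the 100 samples with ω = 2π/100 — exact on a
uniform grid (equivalent to the DFT bins) and an exact inverse of the
synthesis for noise-free cycles (≤ 1e−6). Harmonic power defaults to the
amplitude convention √(Aₙ² + Bₙ²); squared and ratio-to-A₀ conventions are
available because the field does not use a single definition. Powers are
invariant to circular phase shifts and, for orders ≥ 1, to constant
offsets.

Characteristic waveforms use K-means with k = 2 within subject (dominant
morphology vs artifacts; centroid of the most populous cluster, ties to
the lowest label) and the plain mean (k = 1) when pooling; k and seeds are
configurable, as neither the clustering level nor k is standardized.

Group differences use the two-sided independent-samples t-test, Student's
pooled-variance form by default (Welch behind a flag). The three per-order
tests are reported unadjusted as the primary result — they are separate
prespecified contrasts — with a Bonferroni column alongside for reference.
The degenerate all-equal case reports t = 0, p = 1 by convention.

## Classification

Features are the subject's 100-point representative waveform; harmonic
powers can replace or augment them behind a flag. The primary model is a
random forest (100 trees, a common default) with class weights
{non-LVE: 1, LVE: 4}; the weights counter the ≈ 3:2–3:1 group imbalance
and demonstrably do not reduce LVE recall relative to unweighted training
on the imbalanced synthetic benchmark. Baselines: an RBF-kernel SVM
(standardized inputs, default regularization) and a two-hidden-layer
(64, 16) ReLU perceptron — the neural baseline is a fully *connected*
network even where the field's naming suggests "FCNN". SVM scores are the
logistic squash of the decision margin, a monotone (hence ROC-preserving)
map into [0, 1]. Splits are stratified 80/20; cross-validation is
stratified fivefold with the unweighted mean over folds; pooled
out-of-fold predictions are also exposed because a single AUC over all
folds has far lower variance than the per-fold mean — null-control tests
use the pooled form averaged over several label permutations.

On the default, deliberately overlapping group distributions the
waveform-only classifiers perform modestly (the first-order power gap is
≈ 0.3 of an SD); the relative ordering of the three model families on
such cohorts is seed- and design-dependent, so the pipeline reports all
three accuracies without asserting an ordering.

## Regression network

The regressor is a small densely connected network: block n + 1 consumes
the concatenation of the input and all previous block outputs, and each
block applies batch normalization, ReLU, then an affine map. Hidden
widths are 128 and 32 with dropout (rate 0.2, a standard default) between
the two hidden blocks; the output is a single linear unit. Disabling
dense connectivity changes the parameter count exactly by the
concatenation arithmetic, which is checked structurally.

Training: Adam with learning rate 0.001, ρ₁ = 0.9, ρ₂ = 0.999, δ = 1e−8
(a second epsilon-like constant of 0.001 that sometimes accompanies
published Adam settings has no defined role in the update rule; it is
recorded in the config but unused), MSE loss, 100 epochs, batch size 128,
and a 10 % validation split carved from the training data. Targets are
standardized internally during training and predictions mapped back —
this conditions the optimization (raw LVDdI ≈ 35 mm/m² would need
thousands of bias steps at this learning rate) without changing the model
class; the loss history is reported on the original mm/m² scale.
Gradients were verified against central finite differences. Non-finite
loss aborts with a diagnostic; predictions are clamped at a small
positive floor (0.1 mm/m²). The loss-history trend check uses a 10-epoch
moving average and tolerates increases up to 5 % per step, since
full-batch Adam oscillates slightly on the converged plateau.

Evaluation: MAPE = (100 %/n) Σ|(ŷ − y)/y| with accuracy = 1 − MAPE
reported as a fraction (it can be negative for MAPE > 100 %; display
clipping is left to callers); confusion-derived accuracy from thresholded
predictions is a *different* quantity and both are reported separately.
Bland–Altman limits are mean ± 1.96 SD of the differences (ŷ − y), with
the fraction of points inside the limits reported. Thresholding predicted
LVDdI into labels inherits the strict sex-specific cutoffs; the ROC score
is the signed margin to the subject's own threshold, logistically
squashed so both sexes share one score axis (monotone, so the AUC is
unaffected).

On the deterministic-LVDdI cohort with harmonic-power features the
default recipe reaches held-out MAPE ≈ 6 % (accuracy ≈ 0.94) —
parameter recovery well inside the 10 % target.

## Evaluation conventions

Positive class is LVE throughout; the per-class table treats each class
in turn as positive. Zero-denominator metrics are reported as undefined
(None), never as 0. Display rounding is two decimals, round-half-even.
The ROC sweep visits each distinct score once (ties move the operating
point in a single step), and the trapezoidal AUC then equals the
rank-average Mann–Whitney statistic exactly — both routes are compared by
brute force in the tests. The pipeline orchestrator persists every
stage's tables, writes plots, and records seeds, a configuration hash,
and a hash of the rounded numeric report, so a rerun with the same
configuration reproduces the same numeric hash.

## Problem sizes

Cohort-scale experiments use the study-design sizes (137 + 90 qualified
subjects; the 264-subject flow fixture); benchmark cohorts for the
classifier property tests use 80–160 subjects, which is sufficient for
the assertions they make (exact contracts, paired comparisons, and
permutation nulls averaged over several permutations).

## Known limitations

- Waveform realism is Fourier-sum realism; no reflected-wave physiology.
- Segmentation assumes foot-aligned, roughly periodic beats; no
  arrhythmia handling beyond the validity flag.
- The harmonic-power magnitudes of the generator are specified on the
  pre-normalization amplitude scale; on the normalized 0–100 scale the
  same shapes have much larger first-order amplitudes, and no single
  published convention reconciles the two — hence the configurable power
  convention and the physical-scale round-trip as the quantitative
  anchor.
- The dense net is a small fully connected variant of dense connectivity;
  convolutional dense blocks with pooling are out of scope.
- Trained models are not serialized; training takes seconds at these
  problem sizes and all predictions and metrics are persisted as text.
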