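# Methods

`navdecode` re-implements, as a tested library, a multi-voxel pattern
analysis (MVPA) of walking-direction signals recorded during free
navigation in a circular virtual arena. Because the analysis is usually run
on data that cannot be redistributed, the package pairs every analysis
stage with a synthetic generator that reproduces the statistical structure
the analysis assumes. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not establish.

## Task model

The behavioral task is a spatial-memory paradigm: participants navigate a
circular grass-plane arena (distances in *virtual meters*, vm; 1 vm = 62.5
Unreal engine units) and repeatedly place five remembered object locations.
One session's feedback phase presents each of the 5 objects once per
repetition, in pseudo-random order, for 6 repetitions — 30 feedback trials.
Performance on a trial is the mean Euclidean distance error over the
non-missing responses; trials with all responses missing are flagged, never
scored as zero. Learning is summarized as log(first-trial error) −
log(last-trial error), natural log (positive = improvement). Log
transformation precedes all group statistics because raw distance errors
are right-skewed.

Group-level chance for the placement task is Monte-Carlo: a pool of 1e5
area-uniform locations is drawn once from the arena disk, the task is
simulated 1000 times with every response replaced by a pool draw, and each
simulation contributes one group-mean error per trial. Area-uniform
sampling uses r = R·sqrt(u); sampling the radius uniformly instead would
concentrate mass near the center and bias chance errors downward. Two
closed-form anchors calibrate this machinery: the mean distance of an
area-uniform point from the center is 2R/3, and the mean distance between
two independent area-uniform points is 128R/(45π) ≈ 0.9054 R.

### Trajectory generator

The original task logs continuous joystick navigation; the generator
replaces it with a wrapped-Gaussian heading random walk: heading diffuses
with volatility `turn_volatility` (deg/√s), position integrates speed
along the heading (speed has multiplicative log-normal jitter), and the
agent steers smoothly toward the arena center when it approaches the wall.
`heading` is the movement direction (not a separate camera yaw); this is
the quantity the decoder targets. Defaults: 10 Hz sampling, mean speed
2 vm/s, volatility 40 deg/√s, session duration 1041.6 s (17.36 min of
free navigation, the average usable navigation time per session in the
study design this emulates), arena radius 25 vm. Volatility 40 deg/√s
yields direction-bin dwell times on the order of 1–3 s, which produces a
realistic number of classifier examples per session (roughly one hundred
per 300 s); the dwell-time distribution is exposed through the extracted
events and should be checked when parameters are changed.

## BOLD model

Each voxel of a simulated region has a preferred direction (uniform on
[0, 360)) and responds to heading h through a circular-Gaussian tuning
profile exp(−d²/2σ²), d the signed circular difference to the preference.
Volume v of a tuned voxel is

    baseline + gain · ⟨tuning response over the volume's acquisition
    window, shifted earlier by the hemodynamic lag⟩ + drift + noise

with TR = 2.36 s and lag fixed at two volumes (4.72 s). The lag is a pure
temporal shift rather than an HRF convolution because the decoding-side
correction is itself a fixed two-volume shift; a canonical double-gamma
convolution mode exists (`hrf_convolve=True`) for robustness checks. Drift
is a set of three shared slow cosines (periods 300/180/120 s) with
per-voxel loadings; noise is iid Gaussian per voxel and volume, with an
optional AR(1) component (`ar_coef`) because temporal autocorrelation is
the main route by which contiguous cross-validation folds could leak.
Confound columns shipped with each run are the generative drift components
plus two fast sine regressors and a framewise-displacement-like column —
stand-ins for the aCompCor/motion regressors a real preprocessing pipeline
would provide. No spatial structure is simulated: voxels have no geometry,
so spatial smoothing is out of scope and must happen upstream when real
volumetric data are supplied.

Key knobs and what they stand in for:

| parameter        | default | role |
|------------------|---------|------|
| `tuning_sd`      | 30°     | representational specificity; widening it emulates age-related dedifferentiation (older-adult-like condition uses 60°) |
| `gain`           | 1.5     | neural gain, the hypothesized locus of dopaminergic modulation; the drug-like condition uses 2.5 |
| `noise_sd`       | 4 a.u.  | measurement noise relative to a baseline of 100 a.u. |
| `fraction_tuned` | 0.5     | proportion of voxels carrying any direction signal |
| `n_voxels`       | 200     | region size (on the order of a retrosplenial ROI) |

With these defaults the low-gain condition decodes at ≈ 18–19 % balanced
accuracy and the high-gain condition at ≈ 22–23 %, against a 16.66 %
chance level — the same regime as published direction-decoding work, where
accuracies sit a few points above chance. The gain pair (1.5 vs 2.5) was
fixed while designing the generator: a smaller pair (1.0 vs 1.5)
reproduces a ~1-percentage-point drug effect but is too weak to recover
reliably from 50 synthetic subjects, and the package's validation suite is
meant to demonstrate recoverability under its default conditions.

## Signal cleaning

`clean_signal` applies, in order: per-voxel linear detrend; projection
onto the complement of a discrete-cosine (DCT-II) basis containing every
component with period > 128 s; OLS regression of up to 10 confound
columns (rank-deficient confound sets lose their collinear columns with a
warning); per-voxel z-scoring. Voxels with zero residual variance are
flagged and zeroed rather than divided by zero. The DCT high-pass is the
SPM-style drift model; note its quadrature property: a stop-band sinusoid
is fully removed only in the cosine phase of the basis, while an
orthogonal-phase component is attenuated but not annihilated (classical
spectral leakage of truncated cosine bases). The Butterworth filter that
nilearn applies for the same cutoff behaves differently in this respect;
the DCT projection was chosen because it is the drift model whose
stop-band behaviour the test suite can state exactly.

## From trajectory to classifier examples

Direction is binned into six half-open 60° bins with edges at multiples
of 60° and center labels 30°, 90°, …, 330°; every finite heading maps to
exactly one bin and binning is 360°-periodic. A *direction event* is a
maximal run of consecutive samples in one bin moving at ≥ 0.05 vm/s
(standing still is not walking), kept if it lasts ≥ 1 s. Each event uses
every volume whose acquisition window overlaps the event interval, shifted
two volumes later; multi-volume patterns are averaged so each event
yields one example. Events whose shifted volumes fall past the end of the
run are dropped and counted. The lag anchor is the event onset (most
literal reading of a fixed post-event sampling offset); an event-midpoint
anchor is available (`anchor="midpoint"`).

Because examples average TR-grid-aligned acquisition windows rather than
the event interval itself, boundary volumes mix in walking from
neighbouring directions; under free navigation typical example "purity"
is 70–90 %, which caps even noiseless decoding around 80–85 % balanced
accuracy. This is a property of the TR-window method itself, not of the
simulator — perfect decoding is only reachable when direction changes are
aligned to the volume grid (the test suite constructs exactly that case).

Sessions are gated before decoding: every bin must have ≥ 3 examples and
every contiguous temporal fold must contain every bin, else the session is
excluded — the synthetic mirror of excluding participants whose walking
did not cover the direction space. The threshold is a config value; the
quantitative criterion used in the original analyses is not public, so
this default is an explicit guess.

## Decoding

Multinomial logistic regression (L2, C = 1, tol = 1e-4, ≤ 1000
iterations, lbfgs) on three contiguous temporal folds per session.
Contiguous folds limit leakage through temporal autocorrelation; a
stratified-random alternative is deliberately not the default. Training
classes are balanced by seeded upsampling with replacement (originals
always retained); balanced accuracy (mean per-class recall) is computed on
the pooled held-out predictions, with per-fold scores reported secondary.
Chance is exactly 1/6, displayed as 16.66 %. Per-session significance uses
a permutation null: the full cross-validation repeated 1000 times with
training labels freshly permuted each iteration (test labels untouched);
group nulls average subject nulls iteration-wise. Permutation p-values use
the add-one estimator (1 + #{null ≥ obs}) / (1 + n), which cannot be zero.
Solver non-convergence at the iteration cap is a warning, not an error:
the iteration budget is part of the classifier contract.

One calibration caveat is inherent to cross-validated permutation nulls:
with few examples per class the null mean of (balanced) accuracy sits
slightly *below* nominal chance, because class proportions in the training
and held-out parts of a finite session anticorrelate. In this pipeline the
effect is about −0.6 percentage points at 240 s sessions (~90 examples)
and vanishes by ~480 s (~165 examples); the shipped calibration experiment
uses 480 s sessions. This is a property of the procedure, not a defect —
which is exactly why chance should be assessed against the permutation
null rather than against the analytic 1/6 when sessions are short.

## Tuning functions

Held-out class probabilities are aligned by the signed circular offset of
each class from the true class — (−120, −60, 0, 60, 120, 180)°, the
antipode mapped to +180 — and averaged into the session's confusion
function. Precision is estimated by least squares against
g(x) = exp(−τx²/2)/Z with Z normalizing g over the six offsets, so the
model sums to one exactly as the confusion function does; this makes the
fit one-parameter. τ is in deg⁻² (conversion helper to rad⁻² provided);
the search interval is [0, 1] deg⁻², bracketed on a log grid seeded by a
moment estimate and polished by bounded Brent to ~1e-12. A free-amplitude
two-parameter variant (`free_z=True`) exists for sensitivity analysis.
One-hot (delta-like) confusion functions make τ non-identifiable above
~0.01 deg⁻² — the SSE is flat at zero — so such fits are pinned to the
upper bound and flagged `converged=False`.

A saturation property matters when interpreting τ̂: with 60° class
spacing, the discrete confusion function stops sharpening once the
generative tuning width is well below the bin width, so τ̂ discriminates
widths above ≈ 20–30° much better than below. The validation suite's
monotonicity experiment (widths 20/40/80/160°) therefore runs in a
high-SNR, steady-walking regime (noise 0.5, gain 2.0, volatility
20 deg/√s, 700 s sessions, 10 subjects) where the ordering is reliably
recovered; at the default noise level the 20° and 40° conditions are not
distinguishable.

## Group statistics

The package implements the simple inference layer: one-sided one-sample
t-tests of per-subject balanced accuracy against 1/6, one-sided
permutation exceedance tests, Bonferroni–Holm correction across regions or
conditions, and paired within-subject condition contrasts. The factorial
linear mixed models used for intervention × age × region × order analyses
are intentionally delegated to dedicated statistics software: `run_study`
writes a tidy long-format table (subject, age_group, session, order,
intervention, roi, balanced_accuracy, tau, fd, …) that is the direct input
for such models, e.g. `accuracy ~ intervention * age_group * roi * order +
(1 + intervention | subject)`.

## Reproducibility

Every randomized stage derives its seed from the study's master seed via
SeedSequence spawn keys (subject index, session index, stage code), so a
study re-run from one config is byte-identical; the run manifest records
the config hash and package version. The voxel population (preferences and
tuned subset) is keyed by subject only, making sessions of one subject
share their tuning structure — the physiological premise of within-subject
drug contrasts.

## Problem sizes used in validation

The shipped test suite and `scripts/acceptance.py` run the same pipeline
at reduced scale, chosen as the smallest sizes at which each statistical
claim is still sharply testable: 300–700 s sessions, 16–96 voxels, 20
subjects × 1000 iterations at 480 s for permutation-null calibration (the
script uses 12 × 400), 50 subjects for the paired gain contrast, 2000
score-level replicates for type-I-error calibration, and 1e5-point pools
with 300 simulated task runs for behavioral chance. Full-scale defaults
(17.36 min sessions, 200 voxels, 1000 iterations) run the same code paths.

## Known limitations

- Voxels have no spatial layout: no smoothing, no spatial noise
  correlations, no ROI geometry effects.
- The null noise model is Gaussian; physiological structured noise beyond
  slow drift + optional AR(1) is not simulated, so passing calibration
  here does not guarantee calibration under, e.g., respiratory artifacts.
- The behavioral generator's learning model (geometrically decaying
  placement noise) is a convenience; it produces monotone learning curves
  by construction and should not be used to study learning dynamics.
- τ̂ saturates below the bin width (see above); comparisons of very sharp
  tuning regimes require finer direction binning than six classes.
- Synthetic validation demonstrates internal consistency (the pipeline
  recovers what the generator encodes); it cannot certify performance on
  real BOLD data with different noise physics.
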