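# Methods

`cevast` implements a quantitative pipeline for assessing celiac disease
(CeD) severity across the whole small intestine (SI) from video capsule
endoscopy (VCE) frames, together with a synthetic data generator and a
simulated expert-reader protocol so the entire analysis can be exercised
and validated without clinical videos.

## The severity model

Severity is expressed on the CeVASt-style 4-point ordinal scale (0 no
disease, 1 mild, 2 moderate, 3 severe), treated as a continuous quantity in
[0, 3] for curve fitting.  Position along the SI is normalized: p = 0 at
the last pyloric frame, p = 1 at the first cecal frame.  The object of
inference is the severity curve s(p): disease burden as a function of
position.

### Synthetic ground truth

Celiac enteropathy is proximal-predominant and patchy.  The generator
realizes this as

    s(p) = clip( S0 · exp(−k p) + patch(p), 0, 3 )

with proximal baseline S0 ∈ [0, 3], decay rate k ≥ 0, and `patch` a
zero-mean smooth Gaussian process with standard deviation `a` and
correlation length `ℓ` (realized as Gaussian-smoothed white noise on a
2048-point latent grid, unit-normalized, so only smoothness and amplitude
are contractual).  Cohorts sample (S0, k, a, ℓ) per patient from
S0 ~ U(0.2, 3), k ~ U(0, 2), a ~ U(0.1, 0.5), ℓ ~ U(0.1, 0.3), spanning a
clinical spectrum from near-normal mucosa to severe proximal atrophy with
moderate patchiness.  Frame positions are stratified-jittered uniform
(one frame per stratum (i + U(0,1))/n), which guarantees strictly
increasing positions without modeling capsule transit time.

### Frame rendering and the texture proxy

Real scoring reads villous texture: healthy mucosa shows a fine mosaic,
atrophic mucosa is flat.  The renderer emulates exactly — and only — this
monotone texture-coarsening.  A frame is a random-phase field: Fourier
phases are drawn from the seed, while the amplitude spectrum is a fixed
Gaussian low-pass whose spatial scale σ(s) = 0.6 + 0.8·s pixels grows with
severity.  The field is normalized, mapped to luminance 128 ± 28, and
tinted (gains 1.0/0.80/0.62 for R/G/B) to resemble mucosa.

The texture statistic T is the RMS circular nearest-neighbour difference of
the contrast-normalized geometric-mean grayscale, averaged over the two
axes.  Because the amplitude spectrum is deterministic given severity, T
varies across renders only through uint8 quantization; it is strictly
monotone decreasing in severity and invariant under all eight dihedral
orientations.  T is inverted to a severity estimate through a calibration
table (mean T over a fixed seeded bank of renders at 31 severity levels,
cached per image size).  The resulting training-free "oracle" estimator has
RMSE < 0.01 against the rendered severity, so in oracle-scored studies the
injected observation noise is the controlled, dominant error source.

What the generator deliberately does not model: bubbles, debris, poor
preparation, illumination falloff, circular field-of-view masks, lesions of
complications (lymphoma/adenocarcinoma), or any photorealistic villous
morphology.  Passing tests therefore demonstrate that the *pipeline
machinery* (scoring contract, ensembling, error-weighted fitting, reader
protocol, agreement statistics) behaves correctly under controlled
conditions — not that any scorer generalizes to real endoscopic imagery.

## Pre-processing

Frames are center-cropped (extra odd-margin pixel goes bottom/right),
converted to grayscale by the per-pixel geometric mean (R·G·B)^(1/3)
computed in floating point, and stamped with the frame's position encoded
8-bit (round-half-up of 255·p) into the top-left 16×16 block.  The stamp
overwrites image content; scorers may legitimately read it (the texture
stem decodes it as a feature), since position is genuinely informative
for proximal-predominant disease.

## Frame scoring

Two backends sit behind one `score_frame` contract returning (severity ŷ
clipped to [0, 3] at inference only, predicted error ê floored at
ε = 0.01).

**Oracle scorer** — inverts T and adds Gaussian noise with chosen SD; the
noise is seeded from the frame's pixel content so inference is
deterministic per frame while orientations draw independent noise.  All
pipeline-level results use this backend; the method under study is the
pipeline, not any particular set of trained weights.

**Trainable residual regressor** — a fixed multi-scale stem (gradient /
Laplacian / dispersion statistics over a 4-level pooling pyramid of the
contrast-normalized frame, stamp rows excluded, plus the decoded position)
feeding a 4-stage residual MLP.  The stage schedule and base width are
configurable; the desk default (1,1,1,1)×8 trains in seconds on a CPU,
while the full-scale reference schedule (3,4,6,3)×64 remains available.
Training is two-phase:

* phase 1 minimizes mean squared severity error;
* phase 2 adds the error head and minimizes
  `|y − ŷ| + w · | |y − ŷ| − ê |`, with w ramped linearly 0 → 100 over the
  phase, so error prediction dominates the objective by the end.

Numerical choices: full-batch Adam (lr 3e-3, phase 2 scaled by 0.3),
decoupled weight decay 1e-3 on weight matrices, subgradients for the L1
terms, ê parametrized as ε + softplus(z) with the error-head bias
initialized at −4 so the untrained head outputs ≈ ε while keeping a live
gradient.  Training is deterministic given the config seed.  The L1 error
loss drives ê toward the conditional *median* absolute error, so mean ê
slightly undershoots mean absolute error on held-out data; it remains
within a factor of two.

## Dihedral ensembling

Each frame is scored in the 8 orientations of the square (4 rotations × 2
flips).  The ensembled severity and error are the (1/ê)²-weighted means of
the per-orientation values; the *orientation spread* is the population
(÷8) standard deviation of the 8 severity predictions, a model-free
uncertainty estimate.  The ε floor on ê keeps weights finite.

## Net error and curve fitting

At evaluation position p₀ the curve value is the inverse-variance weighted
mean of in-window frames, w = 1/net_error², window total width 1/9 SI
(half-width 1/18).  Net error combines independent components in quadrature
(root-sum-square — the sources are unsystematic, so variances add):

| component | value | applies to |
|---|---|---|
| frame error | a·ê + (1−a)·spread, a = 0.5 | machine reads |
| systematic reader error | 0.1875 | expert reads |
| distance decorrelation | 0.84 · \|p − p₀\| | all |
| discretization | √(1/12) ≈ 0.289 | expert reads; machine reads by default (the regression targets derive from discretized scores, leaving a residual influence) |

The 0.84/SI coefficient is the empirical rate at which severity
decorrelates along the bowel; √(1/12) is the RMS of a rounding error
uniform on [−½, ½] (the package re-derives it by bootstrap).  The blend
coefficient a between the two per-frame error estimates is exposed as
config with default 0.5 (no stated value adopted).  Effective standard
error per grid point is √(1/Σw).  Curves are evaluated on a dense
200-point grid unioned with the 10 comparison points k/9, k = 0..9 —
spaced exactly one window apart, so the comparison values are mutually
independent; empty windows yield missing points.

**Under-dispersion correction.**  Weighted averaging shrinks curves toward
local means, so machine curves can be flatter than truth.  With s_c the SD
of the curve over the comparison points and m the mean squared effective
error, the factor f = √(s_c² + m)/s_c re-inflates deviations from the
patient's mean level when f > 1 (then re-clips to [0, 3]); deflation is
never applied, constant curves are left untouched, and f is recorded.
This specific re-inflation rule is this package's construction (only
one-sidedness is inherited); it can be disabled.

## Derived metrics

From the dense curve: first-tertile mean and max (p ≤ 1/3) and whole-SI
mean, excluding missing points.  Separately, the mean *raw* frame score at
p < 0.05 — sequestered because apparent villous change just past the
pylorus can reflect gastric injury rather than CeD.

## Simulated readers and calibration

A reader perceives s(p) plus Gaussian noise (optional bias), reports
round-half-up clipped to {0..3}.  Sessions group 5–10 videos with all
frames shuffled together, 60 scored frames per video.  The one free
parameter, the noise SD, is set by bisection (common random numbers, hence
deterministic and monotone) so that one reader's simulated MAE against the
3-reader mean score matches 0.1875; with the default target the calibrated
SD is ≈ 0.25, and an unreachable target (scores pin at the scale ends)
raises a calibration error.

## Agreement statistics

Krippendorff's alpha for interval data, coincidence-matrix formulation:
items with < 2 ratings dropped, δ(v,v′) = (v−v′)², alpha = 1 − D_o/D_e,
with alpha = 1 by convention when D_e = 0.  The implementation is verified
in the test suite against an independent brute-force enumeration of all
pairable value pairs.  Interpretation bins: < 0.1 none, 0.1–0.2 slight
(labeling the conventional gap), 0.2–0.4 fair, 0.4–0.6 moderate, 0.6–0.8
substantial, ≥ 0.8 almost perfect (half-open bins).  R² is the squared
Pearson correlation (not regression through the origin), with missing
pairs dropped.  For curve-level alphas each (patient, comparison point)
pair is one item.

## The reference desk-scale study

20 patients; machine read of 2000 frames/video (oracle scorer, noise SD
0.3 per orientation, 8-orientation ensembling); 3 calibrated readers at 60
frames/video; curves fitted per rater; machine curves dispersion-corrected;
panel-average curve = pointwise mean of reader curves, whose metrics
represent the expert panel.  Problem sizes were chosen so the whole study
runs in about a minute on one CPU while every window at every comparison
point is well populated (≈ 220 machine frames, ≈ 7 expert frames).
Reported outputs: alpha for inter-reader curve values, mean-reader vs
machine curve values, and the three derived metrics, plus R² per metric.

## Known limitations

* The oracle scorer reads the very statistic the renderer encodes; it
  validates the pipeline, not image understanding.
* The trainable backend's stem is hand-fixed; only the residual MLP is
  learned.  It is not a convolutional network and makes no claim of
  transfer to real frames.
* Reader simulation is item-independent: no context effect from the short
  preceding/following video segments, no learning or fatigue, no
  systematic per-reader bias by default, and frame skipping is supported
  only as missing values.
* Agreement levels measured on synthetic cohorts depend on the generator's
  between-patient spread and are a qualitative, not numeric, reproduction
  of any clinical result.
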