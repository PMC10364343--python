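# cevast

Quantitative assessment of celiac disease (CeD) severity across the whole
small intestine (SI) from video capsule endoscopy (VCE) frames.

Celiac enteropathy is patchy and proximal-predominant, and conventional VCE
reading is subjective and slow.  `cevast` implements the quantitative
pipeline that turns per-frame ordinal severity scores into a disease-burden
*curve* along the bowel, and the statistics used to compare machine reads
with expert reader panels.  It is aimed at researchers developing or
evaluating automated VCE scoring: everything runs on synthetic cohorts with
known ground truth, so no clinical data is required.

## What it computes

* **Frame scoring** on the 4-point scale (0 none, 1 mild, 2 moderate,
  3 severe) with a per-frame predicted error ê, via a training-free oracle
  scorer for synthetic frames or a trainable residual regressor with the
  two-phase loss `|y − ŷ| + w·||y − ŷ| − ê|`, w ramped 0 → 100.
* **Dihedral test-time ensembling**: each frame scored in the 8
  orientations of the square, combined with weights (1/ê)², reporting the
  orientation spread as a second uncertainty estimate.
* **Severity curves**: at each position p₀, the inverse-variance weighted
  mean of frames within a 1/9-SI window, with per-frame *net error*
  combining prediction error, distance decorrelation (0.84 severity units
  per SI length), discretization error (√(1/12) ≈ 0.289) and systematic
  reader error (0.1875) in quadrature; one-sided under-dispersion
  correction; curves compared at 10 points spaced 1/9 apart so their
  windows are disjoint.
* **Derived metrics**: first-tertile mean and maximum, whole-SI mean, and
  the sequestered mean score of the first 5 % of the bowel.
* **Reader simulation**: 3-expert panels scoring 60 shuffled frames per
  video, with noise calibrated so an individual's MAE against the panel
  mean is 0.1875.
* **Agreement statistics**: Krippendorff's alpha for interval data with
  missing values (verified against brute-force pair enumeration),
  interpretation bins, and R².

## Worked example

Score a dense synthetic video with the oracle scorer, fit the severity
curve, and read off the derived metrics:

```python
import numpy as np, pandas as pd
from cevast import (ProfileParams, SeverityProfile, render_frame, OracleScorer,
                    score_frame_ensembled, fit_curve, comparison_points,
                    correct_underdispersion, tertile_metrics)

profile = SeverityProfile(ProfileParams(s0=2.8, k=1.5, a=0.4, corr_length=0.2),
                          seed=3, patient_id="demo")
rng = np.random.default_rng(0)
n = 1000
pos = (np.arange(n) + rng.uniform(0, 1, n)) / n
model = OracleScorer(noise_sd=0.3, seed=1)
rows = []
for p, s in zip(pos, profile.eval(pos)):
    fs = score_frame_ensembled(model, render_frame(float(s), 64,
                                                   seed=int(rng.integers(2**31))))
    rows.append(("demo", p, fs.severity, "mla", fs.error, fs.orientation_spread))
obs = pd.DataFrame(rows, columns=["patient_id", "position", "score", "source",
                                  "pred_error", "orientation_spread"])
curve = correct_underdispersion(fit_curve(obs))
m = tertile_metrics(curve)
print("comparison points:", np.round(comparison_points(curve), 2))
print("truth at points:  ", np.round(profile.eval(np.arange(10) / 9), 2))
print(f"first tertile mean={m.first_tertile_mean:.2f} max={m.first_tertile_max:.2f} "
      f"SI mean={m.si_mean:.2f} dispersion factor={curve.dispersion_factor:.3f}")
```

prints

```
comparison points: [2.89 2.88 2.5  1.92 1.53 1.28 1.09 0.95 0.87 0.86]
truth at points:   [3.   3.   2.49 1.9  1.53 1.28 1.1  0.96 0.87 0.82]
first tertile mean=2.60 max=2.89 SI mean=1.66 dispersion factor=1.001
```

The fitted curve tracks the latent severity profile to within a few
hundredths of a severity unit at the 10 independent comparison points
(the small shortfall at p = 0 is boundary shrinkage of the windowed fit);
the metrics summarize proximal (first-tertile) and whole-bowel burden.

The same workflow is available from the shell:

```sh
cevast simulate --out cohort/ --n-patients 5 --frames-per-video 200 --seed 7
cevast score --cohort cohort/ --out scores.csv --noise-sd 0.3
cevast fit --scores scores.csv --out curves.csv
cevast metrics --curves curves.csv --scores scores.csv --out metrics.csv
cevast plot --curves curves.csv --out figures/
cevast run-all --out study/ --seed 1        # complete study incl. reader panel
```

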