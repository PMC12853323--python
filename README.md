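# tendondti

Reliability and repeatability analysis for tendon diffusion tensor
imaging (DTI), built around the patellar tendon: synthetic phantom
cohorts, per-voxel tensor estimation, anatomical region partitioning, and
mixed-model reliability statistics.  It is aimed at musculoskeletal
imaging researchers who want to (a) prototype and validate a tendon DTI
analysis chain before scan data exist, and (b) run the same chain on real
NIfTI + bval/bvec data once they do.

## The analysis

Water diffusion in each voxel is modelled as a symmetric positive tensor
D estimated from the signal model

    S(b, g) = S0 · exp(−b gᵀ D g),

fit per voxel by weighted log-linear least squares and refined by a
damped Gauss–Newton (Levenberg–Marquardt) iteration on the un-logged
model (optionally constrained positive-definite through a Cholesky
parameterization).  Sorted eigenvalues give the axial (λ1) and radial
(λ2, λ3) diffusivities, MD = (λ1+λ2+λ3)/3, and

    FA = sqrt(3/2) · sqrt(Σᵢ(λᵢ − MD)²) / sqrt(Σᵢ λᵢ²).

Tendon masks drawn on a high-resolution anatomical grid are partitioned
into six regions: the whole tendon; medial / central / lateral thirds of
equal width along each slice's greatest cross-sectional diameter, with
boundaries perpendicular to it; and proximal / distal halves of equal
length (an odd middle slice belongs to both).  Region masks are
downsampled to the DTI grid by exact volume-occupancy (threshold 0.5) and
eroded by one in-plane boundary pixel before metrics are extracted.

Reliability of each region × metric is summarized by the consistency
intraclass correlation from a linear mixed model — rating (rater or scan
session) as a fixed effect, participants as random intercepts, REML —

    ICC = σ²_participant / (σ²_participant + σ²_residual),

with participant-resampling bootstrap confidence intervals, the standard
error of measurement SEM = SD·sqrt(1 − ICC), qualitative bins
(poor < 0.50 ≤ moderate < 0.75 ≤ good < 0.90 ≤ excellent), an optional
pooled model with limb type as an additional fixed effect, and
leave-one-participant-out sensitivity.  The companion sample-size
calculator uses the Walter–Eliasziw–Donner approximation.

Because no public tendon DTI dataset accompanies this design, the
`phantom` module simulates the full study: 10 participants × 2 limbs
(tendinopathy or BPTB graft-harvest limb + healthy contralateral) ×
2 sessions, two raters on session 1, Rician noise at SNR 30, and a
session model whose region-mean diffusivity ICC equals a designed value
in expectation.  See `docs/methods.md` for the models and their limits.

## Worked example

```python
import pandas as pd
from tendondti import CohortSpec
from tendondti.pipeline import RunConfig, run_reliability_study

cfg = RunConfig(cohort=CohortSpec(n_subjects=10, seed=7),
                fit_mode="nonlinear", n_boot=200, outdir="example-run")
paths = run_reliability_study(cfg)

tab = pd.read_csv(paths["icc_retest"])
print(tab[tab.region == "whole"]
      [["limb", "metric", "icc", "ci_low", "ci_high", "sem", "class"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

prints the whole-tendon test–retest table of the synthetic cohort:

```
         limb  metric   icc  ci_low  ci_high   sem     class
contralateral lambda1 0.942   0.687    0.988 0.011 excellent
contralateral lambda2 0.925   0.700    0.981 0.010 excellent
contralateral lambda3 0.851   0.704    0.936 0.010      good
contralateral      md 0.938   0.778    0.986 0.009 excellent
contralateral      fa 0.738   0.031    0.877 0.008  moderate
contralateral  volume 0.976   0.910    0.997 0.014 excellent
 pathological lambda1 0.761   0.482    0.875 0.032      good
 pathological lambda2 0.788   0.425    0.915 0.025      good
 pathological lambda3 0.427   0.000    0.769 0.019      poor
 pathological      md 0.749   0.354    0.913 0.023  moderate
 pathological      fa 0.358   0.000    0.829 0.011      poor
 pathological  volume 0.962   0.926    0.987 0.015 excellent
```

Each row is one DTI metric in one limb: the ICC point estimate, its
percentile-bootstrap 95 % CI, the SEM in the metric's own units
(diffusivities in 10⁻³ mm²/s), and the qualitative class.  The cohort
was designed with true retest ICC 0.35 for pathological and 0.80 for
contralateral limbs; with only 10 participants the per-cohort estimates
scatter widely around those values (this seed lands high in both limbs),
but the ordering — pathological diffusivities less repeatable than
contralateral, mask volumes nearly perfectly repeatable — is exactly the
pattern such a study reports on real tendons.  The inter-rater table
from the same run puts every DTI metric at ICC ≥ 0.977 (excellent):
identical scans segmented by two simulated raters disagree far less than
the same tendon scanned on two days.  `example-run/` also receives the
SEM tables, wide report tables, the measurement CSV, and a manifest with
the config hash and seeds.

The same stages are available from the shell:

```sh
tendon-dti init-config -o study.yaml
tendon-dti run-all -c study.yaml -o out/
tendon-dti fit --dwi dwi.nii --mask support.nii -o maps/   # real data
tendon-dti rois --mask tendon.nii -o rois/
```

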