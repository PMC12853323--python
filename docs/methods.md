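# Methods

`tendondti` implements a complete test–retest reliability analysis for
tendon diffusion tensor imaging (DTI) — phantom cohort generation, tensor
estimation, tendon region geometry, region statistics, and mixed-model
reliability statistics.  This note records the models, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Study design emulated by the phantom

The cohort generator reproduces the layout of a bilateral patellar-tendon
repeatability study: `n_subjects` participants (default 10), each with a
pathological limb (patellar tendinopathy or a bone–patellar tendon–bone
(BPTB) graft-harvest site; default five of each) and a healthy
contralateral limb; two scan sessions; two independent raters segmenting
the session-1 anatomy and rater 1 alone segmenting session 2.  Anatomy
lives on a 0.5 mm isotropic grid; DTI on a 1.4 × 1.4 × 3.0 mm³ grid with
b = 800 s/mm², 30 diffusion directions (deterministic Fibonacci-sphere
arrangement) and 4 b = 0 volumes.

### Geometry

The tendon is a mildly bowed elliptic cylinder: default 25 slices of
0.5 mm, in-plane semi-axes 6 × 4 mm (12 × 8 voxels), 1.5 mm peak bowing,
15 % distal taper.  Per-subject geometry jitters the radii (8 % CV) and
slice count (±2), which also makes odd and even slice counts both occur
and so exercises the middle-slice duplication rule.  Limb side alternates
across subjects and is opposite between limbs of one subject, exercising
the laterality resolution.

### Tissue model

Each voxel inside the tendon holds `D = R diag(λ1, λ2, λ3) Rᵀ` with the
principal eigenvector along the local centerline tangent.  Healthy
eigenvalues default to (0.93, 0.80, 0.35)·10⁻³ mm²/s, chosen to reproduce
the axial diffusivity (≈ 0.92·10⁻³), mean diffusivity (≈ 0.69·10⁻³) and
FA (≈ 0.41) reported for healthy patellar tendon imaged with an extended
knee.  Pathology is a focal severity field p ∈ [0, 1] (proximal-medial
blob for tendinopathy, central-third band for graft harvest, matching
where those pathologies present) applied as

    D′ = (1 + g·p) · ((1 − m·p) D + m·p · MD · I),   g = m = 0.5,

which raises diffusivity and lowers FA monotonically in p.  The severity
field is renormalized so that its mask average is a limb-class constant
(amplitude/4): without this, the blob–geometry interaction injects
subject-stable variance into whole-tendon means and distorts the
repeatability calibration below.

### Raters

A rater's segmentation is the true mask's signed distance field plus a
smooth zero-mean, unit-variance Gaussian random field (correlation length
2 mm) scaled to the jitter amplitude (default 0.5 mm), re-thresholded at
zero, largest connected component kept.  Real segmentation disagreement
is spatially correlated, which is why the perturbation acts on the
distance field rather than flipping voxels independently.  Inter-rater
agreement is therefore governed by the jitter amplitude; it is not
analytically calibrated (mask-induced metric variance has no closed
form).

### Repeatability calibration

Between-day variation is a per-subject×limb multiplicative diffusivity
factor `1 + a + e_s` with `a ~ N(0, ρσ²)` shared across sessions and
`e_s ~ N(0, (1−ρ)σ²)` drawn per session, σ the total coefficient of
variation (default 5 %) and ρ the designed consistency ICC per limb class
(defaults 0.35 pathological, 0.80 contralateral, mirroring the ordering a
repeatability study of pathological tendons reports).  Because the factor
scales the whole tensor, region-mean diffusivities inherit the variance
split exactly and their consistency ICC equals ρ in expectation; this was
verified empirically (pooled estimate 0.28 over 300 simulated subjects at
ρ = 0.30).  An analogous split on an isotropy-blend coefficient (default
5 % SD) varies anisotropy between subjects and sessions; FA is
approximately, not exactly, calibrated because FA is nonlinear in the
blend.

### Noise

DWI magnitude noise is Rician: `S′ = sqrt((S + n1)² + n2²)` with
`n1, n2 ~ N(0, (S0/snr)²)` and SNR defined on the b = 0 signal (default
30 — a plausible value for a knee-coil EPI acquisition; the noise floor
bias this induces is common to both sessions and largely cancels in
ICCs).  `snr = inf` gives noise-free data.  All randomness flows from a
single seed through `numpy` seed sequences; identical specs give
bit-identical cohorts.

## Tensor estimation

* **Log-linear (initializer).**  `ln S = ln S0 − b gᵀDg` solved per voxel
  by weighted least squares; an ordinary least-squares pass supplies
  predicted signals whose squares form the weights (the standard
  heteroscedasticity correction for logged Rician data).  Non-positive
  signals are clamped to a tiny positive floor and the voxel flagged.
  A design matrix with rank < 7 (e.g. coplanar directions) raises.
* **Nonlinear.**  Levenberg–Marquardt on the un-logged model, batched
  over voxels with a per-voxel damping parameter; steps are accepted only
  when the residual sum of squares decreases, so the fit can never be
  worse than its initializer.  Convergence: relative objective decrease
  < 1e-10 or 100 sweeps; voxels that never converge are flagged invalid
  rather than aborting.  The optional positivity mode parameterizes
  D = LLᵀ through its Cholesky factor (and S0 through its logarithm), so
  eigenvalues are non-negative by construction.  Both constrained and
  unconstrained modes are exposed because published pipelines differ.
* Negative eigenvalues from the unconstrained fit on noisy data are kept
  but the voxel can be excluded downstream via the valid flag; region
  statistics use valid voxels only.

Scalar maps sort eigenvalues descending (λ1 axial; λ2, λ3 radial),
MD = (λ1+λ2+λ3)/3, FA = sqrt(3/2)·sqrt(Σ(λᵢ−MD)²)/sqrt(Σλᵢ²), with FA
flagged undefined for an all-zero tensor.

## Region geometry

* **Greatest cross-sectional diameter**: the longest chord between
  boundary-voxel centers of the slice's largest 8-connected component,
  computed as the diameter of the convex hull (exhaustive pairs over hull
  vertices; all boundary points for small slices).  Ties within floating
  precision resolve to the lexicographically smallest endpoint pair; a
  single-voxel slice has length 0 with the axis defaulting to the first
  in-plane direction.
* **Trisection**: voxel centers project onto the diameter axis; cuts at
  1/3 and 2/3 of the diameter length give boundaries perpendicular to the
  axis.  Voxels projecting exactly onto a cut belong to central.  Slices
  whose diameter is shorter than three in-plane voxels go entirely to
  central — a deterministic rule that avoids meaningless slivers.
* **Laterality**: masks carry the signed in-plane axis pointing to the
  subject's anatomical left plus the limb side; the medial side is the
  subject's left for a right knee and the subject's right for a left
  knee.  Trisection refuses to guess when either field is missing.
* **Bisection**: occupied slices ordered from the proximal end; even
  counts split cleanly, odd counts place the middle slice in both halves.
  Proximal+distal volumes therefore exceed the whole by one slice's
  volume when the count is odd; volumes are reported as computed.
* **Volume** = true-voxel count × voxel volume (reported in cm³).
* **Downsampling** to the DTI grid uses exact axis-separable box
  overlaps: a target voxel is included iff the covered volume fraction is
  ≥ the occupancy threshold (default 0.5; ties included).  Region labels
  transfer by the largest label occupancy among the three longitudinal
  labels within each included voxel, ties resolving to central;
  proximal/distal masks are downsampled independently (they may overlap).
* **Erosion** removes one boundary pixel with a 4-connected structuring
  element *in-plane only*: with 3 mm slices, a 3D erosion would delete
  the end slices outright.  Only the outer tendon boundary is eroded; the
  internal boundaries between regions are not.

## Reliability statistics

* **ICC**: consistency form from a linear mixed model — rating factor
  (rater or session) fixed, participant random intercept, residual —
  fit by REML (statsmodels `MixedLM`);
  ICC = σ²_participant/(σ²_participant+σ²_residual), truncated to [0, 1].
  After the optimizer converges, the estimate is polished by a 1-D Brent
  refinement of the profiled REML criterion in the variance ratio; on
  balanced two-rating data the result matches the classical mean-squares
  ICC(C,1) to ~1e-8.  Data that the additive fixed-effect structure fits
  exactly (zero residual) short-circuit to ICC 1, avoiding a boundary
  fit; fully constant data yield NaN with a warning.
* **Pooled model** adds limb type (healthy / tendinopathy / BPTB) as a
  fixed effect, absorbing class mean offsets that would otherwise inflate
  the pooled ICC; with a single class present it falls back to the plain
  model with a warning.
* **Bootstrap CI**: participants resampled with replacement (keeping all
  their ratings, relabelled uniquely), ICC refit per resample (without
  the Brent polish — the refits need speed, not 1e-8 accuracy),
  percentile 2.5/97.5 bounds over successful refits; failures beyond 20 %
  are recorded as a warning on the result.  Percentile bootstrap at
  n = 10 under-covers somewhat; the coverage check below asserts ≥ 85 %
  rather than the nominal 95 %.
* **SEM** = SD·sqrt(1 − ICC), SD pooled over all observations of the
  stratum (both ratings, all participants).
* **Classification**: poor < 0.50 ≤ moderate < 0.75 ≤ good < 0.90 ≤
  excellent; the bins are left-closed because the conventional wording is
  ambiguous at the boundaries.
* **Sample size**: Walter–Eliasziw–Donner approximation
  `n = ceil(1 + 2k(z_{α/2}+z_β)²/((k−1)(ln C₀)²))` with
  `C₀ = (1+kρ₀/(1−ρ₀))/(1+kρ₁/(1−ρ₁))`.  Defaults ρ₀ = 0, two-sided
  α = 0.05, power 0.80; with ρ₁ = 0.75 and k = 2 ratings this gives
  n = 10, the canonical design size for establishing good reliability.

## Validation scale and what it shows

The test suite runs everything end-to-end at deliberately modest problem
sizes: tensor exactness on 100 random tensors; scalar-map symmetries on
1000; ROI invariants on 200 procedural masks (cylinders, bent tubes,
L-prisms, random blobs) against brute-force oracles; LMM/ANOVA agreement
on 50 balanced tables; ICC recovery at designed ICC ∈ {0.3, 0.6, 0.9}
with 50 replicate 10-subject cohorts per level (whole-tendon MD, both
limb strata, log-linear fits) with the replicate mean required within
±0.1 of the design value; bootstrap coverage at designed ICC 0.8 over 50
cohorts with 200 resamples each on the contralateral stratum; and a
4-subject noise-free smoke run that must produce ICC = 1.000 for every
DTI metric and exact volume additivity.

Passing these shows the pipeline is internally correct and statistically
calibrated under the phantom's assumptions.  It does not show performance
on real tendon MRI: the phantom has no eddy-current or susceptibility
distortion, no fat signal or partial-Fourier artifacts, spatially uniform
tissue within limb class apart from one smooth pathology focus, raters
that differ only by smooth boundary noise, and a noise-free geometric
correspondence between the anatomical and DTI frames (no registration
error).  Real inter-rater and between-day variance structures are richer
than a single multiplicative factor.

## Known limitations

* Inter-rater ICCs emerge from the jitter amplitude; only the retest ICC
  of diffusivity means is analytically calibrated, and FA only
  approximately.
* The realized retest ICC of pathological limbs sits slightly above the
  nominal value because focal pathology adds subject-stable regional
  heterogeneity (whole-tendon means are protected by the severity
  normalization; sub-regions are not).
* Volumes and their ICCs follow from the geometry model and are not
  calibrated to any target.
* The full default study (n_boot = 1000 over 144 table cells) is
  compute-heavy; reduce `n_boot` for exploratory runs.
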