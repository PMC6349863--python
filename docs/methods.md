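# Methods

## Normative model and W-scores

At every location *i* (surface vertex or skeleton voxel) the control cohort
is fit by OLS,

y_i = β₀ + β₁·age + β₂·sex + β₃·ICV + ε,  ε ~ N(0, σ_i²),

all locations at once via a single least-squares solve on the stacked
control matrix. The residual SD uses the df-adjusted denominator n − 4
(intercept plus three covariates). "SD of the residuals" is ambiguous
between the population (ML) and df-adjusted estimator; the df-adjusted form
is unbiased for σ² and makes the in-sample calibration exact: writing
W = e_i/σ̂_i for the fitted controls, Σ e² = (n−4)·σ̂² identically, so each
location's in-sample W-scores have mean exactly 0 and sample SD (ddof = 1)
exactly sqrt((n−4)/(n−1)) — 0.97234 at n = 56, 0.98473 at n = 100,
approaching 1 as n grows. The test suite asserts this identity to 1e-10 and
checks that held-out controls from the same population calibrate to
mean ≈ 0, SD ≈ 1.

Covariate conventions: sex is 0/1 (female = 1), ICV in mm³. All three
covariates are applied to every modality uniformly; nothing in the model
distinguishes surface from skeleton beyond the location index. W-scores are
affine-invariant in the covariates (rescaling age or ICV changes β̂ but not
W), which the suite checks exactly.

Degeneracy: a location whose residual SD falls below 1e-8 times the map's
median absolute value (a relative scale, so MD in mm²/s and thickness in mm
behave alike) is flagged and masked out of W-maps rather than producing
unbounded scores. Rank-deficient designs (e.g. a single-sex control group)
drop the constant column with a warning, set its coefficient to 0 and shrink
the residual df accordingly; this keeps synthetic edge cases runnable while
leaving the full-rank path untouched.

Sign conventions: positive W = thicker cortex / higher FA / higher MD.
`abnormality_direction` records which tail marks damage (thickness and FA
low, MD high) for one-sided reporting; all tests below are two-sided.

## Surface smoothing

Real surface pipelines smooth thickness with a geodesic Gaussian kernel
(FWHM 20 mm). On the toy grid-graph geometry the package uses k passes of
uniform self-plus-neighbour averaging. One pass on a 2-D grid with spacing h
and degree 4 spreads per-axis variance 2h²/5, so k = round(σ²/(2h²/5)) with
σ² = FWHM²/(8 ln 2). At the defaults (FWHM 20 mm, h = 3 mm) k = 20. The
operator is doubly stochastic on a regular closed (periodic) grid, hence
preserves constants exactly and never changes the map mean there; FWHM 0 is
the identity. Rounding k limits FWHM fidelity for very small kernels — at
the default scale the equivalent FWHM is within a few percent of request.

## Skeleton masking, PET and inclusion rules

Skeleton analyses are restricted to voxels with mean FA strictly above 0.2
(boundary excluded; the source criterion does not state boundary semantics,
so the strict form is fixed here and tested). The amyloid-PET global ratio
is the mean uptake over the frontal/parietal/temporal/posterior-cingulate
composite divided by cerebellar uptake, positive iff strictly > 1.5. The
modified-Fazekas rule classifies periventricular/deep WMH extents (mm,
measured radiologically and taken as inputs): ≥ 10 and ≥ 25 → eligible as
sporadic small-vessel cognitive impairment; both < 10 → eligible as control;
otherwise neither.

## Lesion frequency maps

Per-group frequency maps are voxelwise means of the binary mask stack.
Group comparison is a voxelwise pooled-variance two-sample t on the 0/1
indicators, two-sided p from the t distribution with n_A + n_B − 2 df,
flagged at p < 0.001 uncorrected. Voxels with zero variance in both groups
*and* equal means (lesioned in nobody, or in everybody) are excluded as
uninformative; all-of-one-group/none-of-the-other voxels are kept and reach
the significance floor (signed infinite t, p = 0). The t on binary data is
an approximation; its null calibration is verified by simulation at
α = 0.01 where discreteness is mild (at α = 0.001 with n ≈ 20 per group the
discreteness of proportions inflates the rate ~2×, which is a property of
the statistic, not the implementation).

## Mass-univariate inference

Contrasts are pooled two-sample t maps (positive t: first group higher).
Surface contrasts are corrected by Benjamini–Hochberg FDR (step-up over all
in-mask vertices, flags where BH-adjusted p ≤ q = 0.05). Skeleton contrasts
use max-statistic permutation FWE: subject labels are exchanged under the
two-group null, each relabelling contributes max |t| over the mask, and
corrected p = (1 + #{perm max ≥ |t_obs|})/(B + 1), which cannot be zero and
is monotone in |t|. When C(n, n_A) ≤ B the full enumeration replaces random
sampling and p is the exact fraction (a multiple of 1/C(n, n_A)); the suite
checks this against exhaustive oracles at 3+3 and 4+4. Threshold-free
cluster enhancement and cluster-extent inference are deliberately out of
scope. Default B = 5000 (the pipeline config uses smaller values at toy
scale); a seed is required wherever sampling occurs and is recorded in the
provenance file. Corrections are applied within each map, not across the
three pairwise contrasts.

Vertexwise contrasts operate on W-maps that are already covariate-adjusted;
no second-level nuisance regression is applied. One consequence, visible in
the tests: with a large between-group covariate gap (17 years of age) and a
small control group, per-location error in β̂ multiplies the gap into a
correlated between-group shift — var ≈ d'(XᵀX)⁻¹d with d the covariate-mean
difference — so null locations can reach significance. This shrinks with
control-cohort size; the planted-recovery study therefore uses
demographically matched groups to measure FDR behaviour cleanly, while the
pipeline test documents the leverage effect deliberately.

## Global statistics

Per-subject global mean W per modality enters an ANCOVA
`value ~ group + age + sex` (type-II F for the group factor); pairwise group
contrasts come from the same fit with Bonferroni multiplication by the
number of pairs. Normality is checked with the Lilliefors-corrected KS test
(estimated mean/SD; statsmodels' small-sample null tables), with a plain
KS against N(0,1) also exposed since W-scores are nominally standardized.
Variance homogeneity uses Bartlett's test. Groups with zero variance are a
data error for Bartlett; constant samples return p = 0 from the normality
check.

## Synthetic cohort: what it emulates, what it does not

The generator is the package's study-condition definition, not a tuning
surface. Defaults: 56 controls (65 ± 8 y, 55% female — the control
demographics are a free design choice and exposed as configuration),
patient groups of 11 (57 ± 7 y), 15 (72 ± 8 y) and 101 (74 ± 7 y); ICV
1.45 ± 0.12 L; ages redrawn below 18. Maps follow exactly the linear-
Gaussian structure the normative model assumes: thickness baseline 2.5 mm
with −5 µm/yr age slope and 0.25 mm noise, FA 0.45 with −0.002/yr and 0.04
noise, MD 0.80 µm²/ms with +0.003/yr and 0.05 noise; FA clipped to [0, 1]
and thickness/MD to ≥ 0 (rare at these levels). Lesion voxels are
independent Bernoulli draws from per-group probability maps (a uniform
field plus a group-specific hotspot by default) — no spatial correlation, no
registration error, no scanner noise, no non-linear covariate effects.
Passing tests therefore demonstrate correctness of the estimators and error
control under the model's own assumptions, not robustness to realistic
violations of them. Toy geometry: 2000 surface vertices on a 50×40 grid
graph (3 mm spacing), a 20³ voxel grid with a 1184-voxel tract-like
skeleton — a desk-scale analogue of ~41k-vertex hemispheres and a TBSS
skeleton.

## Calibration and recovery studies

`normmap.calibration` runs the quality checks the acceptance machinery
reports: (a) 200 null datasets, 10 vs 10 subjects on 300 locations, 199
permutations — family-wise error ≤ α + 3·SE and voxelwise uncorrected rate
at α = 0.001 within its Monte-Carlo band; (b) 500-replicate type-I rates
for the ANCOVA group F and Bartlett tests; (c) planted-deficit recovery:
Cohen's d = 1.0 on a contiguous 400-vertex patch (a lobe-scale region; the
self-consistent BH power calculation at 30 vs 30 subjects and m = 2000 puts
sensitivity near 0.87, so an 0.80 floor is attainable — a smaller patch
would drive the BH threshold, and the attainable power, below that floor),
150 controls, 12 replicates, reporting mean sensitivity and mean empirical
false-discovery proportion. Problem sizes are chosen so the full suite runs
in well under a minute for these studies while keeping 3·SE Monte-Carlo
bands tight enough to be meaningful.

## Pipeline and formats

The driver runs simulate/load → frequency maps → normative fits → W-maps
(surface maps smoothed first; skeleton analyses FA-masked) → corrected
contrasts → global ANCOVA, writing `models/`, `wmaps/`, `freqmaps/`,
`statmaps/`, `summary.json` and a provenance record (config hash, seed,
versions). Deterministic stages are bit-identical across re-runs.
Covariates and surface maps travel as CSV (header mandatory, UTF-8, '.'
decimal; vertices 0-based), volumes as NIfTI-1 with isotropic affine,
normative models as JSON header + CSV coefficient table, configs as YAML
validated by an explicit checker. Known limitations: no GIFTI/DICOM import,
no site harmonization, no longitudinal W-scores, no nonlinear normative
models.
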