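# Methods

This note documents the models, conventions and numerical choices behind
`liporadiomics`, and what the synthetic phantoms do and do not establish
about real data.

## Problem setting

Intramuscular (IM) lipomas (benign) and atypical lipomatous tumors /
well-differentiated liposarcomas (ALTs/WDLSs, low-grade malignant) share
MRI appearance. The workflow classifies lesions from non-contrast
T1-weighted volumes using 107 radiomic features of the tumor ROI plus the
tumor-to-bone distance, after fat-referenced intensity normalization,
ICC-based reproducibility screening, and L1-penalized logistic
classification with cross-validated penalty selection. Malignant is the
positive class throughout.

## Synthetic phantom generator

No public imaging cohort of these tumor types exists, so the package
generates seeded 3D phantoms (`liporadiomics.phantom`) that reproduce the
class-conditional structure the classifier is supposed to exploit:

| effect | benign (IM lipoma) | malignant (ALT/WDLS) |
|---|---|---|
| minor semi-axis | 3.5–6 mm | 6–10 mm |
| elongation (major/minor) | 1.4–2.2 | 1.0–1.4 (more spherical) |
| septa | none | 1–2 bright sheets, +150 raw units, 1.2 mm thick |
| base histogram skewness | −1 (reflected gamma) | 0 (Gaussian) |
| tumor-to-bone gap | 8–25 mm | 2–12 mm |

Fixed elements: a 64×48×48 grid at 1 mm isotropic spacing; bone modeled
as a flat 3-voxel slab at the low end of axis 0 (no bone segmentation
protocol exists for the distance measurement, so the slab is our declared
stand-in — the simplest geometry that makes the distance feature
informative); muscle background at mean 200; a 6³-voxel fat-reference
cube (mean 500) at the far end; tumor base intensity equal to fat. Every
volume is multiplied by a per-case scanner scale drawn from U(0.6, 1.8),
which makes NIV normalization functionally necessary rather than
decorative. One master seed; case *i* uses the substream
`default_rng([seed, i])`, so cohorts are bit-reproducible and
order-independent.

Two consequences worth knowing. First, the bright septa sit on top of a
skew-0 base, so the *realized* malignant skewness is slightly positive
(about +1.4 at the defaults) rather than exactly near zero; the required
ordering — benign clearly more negative — holds with a wide margin.
Second, the tumor/muscle boundary is a hard intensity step (no
partial-volume blur is simulated), which makes histogram-tail features
more sensitive to boundary re-draws than they would be on real MRI (see
the screening section).

What the phantoms do **not** emulate: MRI physics (bias fields, coil
profiles, partial volume), anatomy (bone is a slab, tumors are
ellipsoids), multi-sequence imaging, or the real covariance structure of
radiomic features. Passing the planted-recovery tests therefore shows the
*pipeline* is correct and sensitive to effects of the planted kind and
size; it does not certify clinical performance.

Observer variability is emulated by `simulate_resegmentation`: each voxel
of the 1-voxel outer shell is added, and of the inner boundary removed,
independently with probability 0.25 (seeded). A full 1-voxel
erosion/dilation is the limiting case of this model and is far harsher
than real re-segmentation.

## Intensity normalization and discretization

NIV = raw / mean(raw over the fat-reference ROI) × 1000, with the plain
arithmetic mean and no outlier trimming. The mean of NIV over the
reference ROI is exactly 1000 by construction.

Texture families need integer gray levels. We use **fixed bin width**
(default 25 NIV units, configurable) with min-shift:
`level(x) = floor((x − min_ROI)/bin_width) + 1`. Fixed bin width is the
convention of the standard radiomics definition set this engine follows;
the default is declared here and recorded in every extraction's config
sidecar, since cross-engine feature values depend on it.

## Feature engine conventions

- **First order (18):** computed on the continuous NIV values; Entropy
  and Uniformity on the discretized histogram. Kurtosis is the raw
  (non-excess) standardized fourth moment. Zero-variance ROIs define
  Skewness = Kurtosis = 0.
- **Shape (14):** surface quantities from a marching-cubes mesh of the
  mask at the 0.5 iso-level in physical coordinates. The binary mask is
  smoothed with a 1-voxel Gaussian before meshing: meshing the raw mask
  overestimates surface area ≈ 9 % (staircase artifact), which would push
  digital-sphere sphericity down to 0.92; with smoothing a radius-20
  digital sphere scores ≈ 0.997 and the surface-to-volume ratio converges
  to the analytic 3/r. Tiny masks whose smoothed field never reaches the
  iso-level fall back to the raw mask. Axis lengths are 4√λ from the
  population covariance eigenvalues of voxel-centre coordinates;
  Maximum2DDiameter{Slice,Column,Row} are the largest in-plane boundary
  diameters over planes perpendicular to axes 0, 1, 2 respectively.
  Disconnected masks use the largest 26-connected component. Note that
  the marching-cubes triangulation resolves ambiguous surface cells
  orientation-dependently, so mesh-derived features are invariant under
  90° grid rotations only to ~1e-4 relative; voxel-derived features are
  exact.
- **GLCM (24):** symmetric co-occurrences at distance 1 over the 13
  unique 3D directions, normalized per direction, features averaged
  arithmetically over directions. Correlation of a constant ROI is 1;
  logs are base 2 with a machine-epsilon guard.
- **GLRLM (16):** run lengths per the same 13 directions, averaged.
- **GLSZM (16) / GLDM (14) / NGTDM (5):** 26-connectivity; GLDM α = 0.
  The GLDM matrix is indexed by the *neighbor* dependence count (an
  isolated voxel has dependence 0), while the size-weighted feature
  formulas use dependence size = count + 1 (center included) so that
  small-dependence emphasis stays finite; this matches the standard
  radiomics definition set's behavior.
- **Distance (1):** minimum voxel-centre-to-voxel-centre Euclidean
  distance between tumor and bone, via a Euclidean distance transform of
  the bone mask (anisotropic spacing respected) sampled at tumor voxels —
  O(N) and exact under the centre convention. Overlap gives 0; an absent
  bone mask yields a *missing* value, never 0.

Every texture family is verified against an independent brute-force
oracle that enumerates pairs/runs/zones/neighborhoods voxel by voxel and
evaluates the defining formulas with scalar arithmetic (1e-9 relative on
all features and fixtures).

## Reproducibility screening

ICC(2,1) from the two-way ANOVA mean squares; negative values are
reported as computed (they always fail the filter). The retention rule is
strict: ICC > 0.75, and when intra- and inter-observer screens both
exist, the **minimum** of the two ICCs must pass. Pearson r and Spearman
ρ are reported descriptively; constant features get undefined
correlations with a recorded reason.

On the default phantoms only ≈ 34/108 features pass the combined screen —
fewer than one would see on real data. The cause is structural: with
min-shifted fixed-width binning and a hard boundary step, a re-drawn
boundary that admits even a few background voxels lowers `min_ROI` by
hundreds of NIV units and relabels every gray level, so low-gray-level
emphasis and histogram-spread features swing wildly. The geometrically
stable features (shape, size, energy, distance) all pass, which is what
the downstream model needs.

## Model

`fit_lasso_logistic` minimizes the average logistic loss plus λ‖β‖₁
(intercept unpenalized, X standardized by the caller) via IRLS with
cyclic coordinate descent and a working-set strategy: the restricted
problem is solved over candidate coordinates, then one full gradient scan
absorbs any KKT violators. Convergence is declared only when the true
(non-quadratic) KKT conditions hold: |scoreⱼ| ≤ λ + 5e-7 for zero
coefficients, |scoreⱼ − λ·sign(βⱼ)| ≤ 5e-7 at active ones. Weights are
clipped at 1e-5; coefficients diverging beyond 1e4 (separable data at
vanishing λ) raise a convergence error with diagnostics.

The CV driver (`cv_select_lambda`) standardizes and refits the selection
inside every training fold (no leakage), over a 100-point log-spaced grid
from λ_max down to 1e-4·λ_max. Two numerical choices: (i) path fits run
in a bounded-effort mode (capped iteration budget, loose stationarity)
because held-out misclassification is insensitive to last-digit
coefficient precision — the chosen λ is then refit at full KKT tolerance
in `finalize`; (ii) grid points where a separable training fold makes the
solver diverge are excluded from selection instead of aborting the run.
Ties at the minimum CV error resolve to the larger (sparser) λ, which
also makes the selection deterministic. The classification threshold is
0.5 and the split is stratified with per-class round-half-up of
n·ratio (a 38/30 cohort at 0.7 gives 48/20); both are configurable, as is
whether reported operating metrics come from the testing set (the
default).

## Evaluation statistics

AUC is the Mann–Whitney statistic (ties ½) with variance from the DeLong
structural components and a normal 95 % CI clipped to [0, 1]; paired AUC
comparison uses the DeLong covariance of both components (identical
scores give z = 0, p = 1 by convention). Binary proportions use exact
Clopper–Pearson intervals. κ comes from statsmodels with an asymptotic
normal CI. Group differences use scipy's two-sided Mann–Whitney U (exact
for small untied samples, tie-corrected normal otherwise) with Bonferroni
adjustment min(1, m·p). Demographic 2×2 tables use Pearson chi-squared
*without* continuity correction, falling back to Fisher's exact test when
any expected count is below 5; continuous covariates use Welch's t-test.
The CI methods for AUC and proportions are a potential source of
CI-width discrepancy against reports that used other constructions.

Readers (human classifiers) are represented as binary scored sets; their
"AUC" is the single-operating-point value computed from the calls. The
analysis scripts demonstrate the comparison machinery with *synthetic*
readers — seeded noisy calls — because no human readings exist for
phantoms.

## Problem sizes

Defaults were chosen so the full test suite runs in a few minutes on one
core: phantom grids of 64×48×48 voxels, cohorts of 68 (38/30) in the
analysis scripts and 200 (100/100) × 20 seeds in the planted-recovery
suite, oracle fixtures ≤ 5×5×5 voxels, 2000 replicates for null
calibration, and n = 500 × 30 replicates for ICC recovery.

## Known limitations

- The phantom classes are more separable than clinical cohorts; CV error
  reaches zero and the selected model can be a single feature. Effect
  sizes are parameters (`ClassParams`), so harder regimes are one config
  away, but the committed defaults are the package's study conditions.
- The ICC retention rate is phantom-specific (see above).
- Reader comparisons are demonstrations of the statistics, not evidence
  about radiologists.
- Mesh-derived shape features carry the marching-cubes conventions
  documented above; absolute values can differ from engines using other
  meshing or smoothing choices, so cross-engine comparisons must state
  the extraction config (which every run records as a JSON sidecar).
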