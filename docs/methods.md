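# Methods

## Standardization

Input volumes are assumed co-registered and spatially normalized to one
common space (declared by `space_tag`; mixing spaces is an error —
registration itself is out of scope, being a solved problem handled by
standard neuroimaging registration tools). Each volume is standardized
against its own occipital reference mask:

    x_sd = (x − x̄_ref) / σ_ref

with the sample (n−1) standard deviation. Per-subject (rather than pooled)
reference statistics are used because the transform is defined per scan;
for reference regions of thousands of voxels the estimator choice is
numerically irrelevant but is pinned for reproducibility. Non-finite
voxels are rejected at load time. The transform makes the reference region
exactly zero-mean/unit-sd, is invariant to affine rescaling of the raw
scan (a·x + b, a > 0), and is idempotent — all three are enforced by
tests.

## Template and striatum mask

The template is the voxel-wise mean of the control-group (NMNC)
standardized maps. Since standardized units already read as "sd above
background", the striatum mask is `mean_map > threshold` with the
threshold in sd units (default 3) applied directly — no second background
estimate is needed. The inequality is strict (a fixed tie-break), and
connected components (26-neighbourhood) smaller than 20 voxels are dropped
to remove speckle that noisy means can leave at the threshold. Raising the
threshold can only shrink the mask.

## VOI definition

Each striatum voxel is described by its across-subject uptake profile
(one feature per subject, groups pooled, no spatial coordinates), so the
clustering tracks pathology-driven covariance rather than anatomy.
K-means (Euclidean, k-means++ seeding, 25 restarts, seeded) is run per
hemisphere for k = 2..7 and the k maximizing the mean silhouette
coefficient is selected, ties toward smaller k. The range starts at 2
because the mean silhouette is undefined for a single cluster; an
unstructured striatum is reported instead via an instability flag when the
best mean silhouette falls below 0.25. Hemispheres are split at the grid
midline (RAS-like convention: higher x = subject right). Clustering per
hemisphere (rather than jointly) guarantees the 2×2
hemisphere-by-gradient output structure when k = 2 wins on both sides.

With k = 2 the higher-mean-uptake cluster is labeled *dorsal* (the dorsal
body carries the template's high-uptake core on the all-group mean
profile), with the superior centroid breaking ties; other k values get
rank labels. VOI volume is voxel count × voxel volume / 1000 (cc).

## Group inference

*VOI level.* Per VOI, an ordinary linear model `uptake ~ group + age`
(cell-means coding, age centered) provides age-adjusted group means and
pairwise contrasts; p-values are one-sided when an expected uptake
ordering (PD < NMC < NMNC) is supplied, and Bonferroni-corrected across
all VOIs × contrasts. Constant within-group ages trigger a warning and
drop the covariate; singular designs are an error.

*Voxel level.* Two-group contrasts use a permutation test with the
Freedman–Lane scheme for nuisance covariates: the data are fitted to the
nuisance-only model, its residuals are row-permuted and re-added to the
nuisance fit, and the full-model t-map is recomputed per permutation.
Each t-map is enhanced with TFCE — the integral over heights h of
e(h)^E · h^H dh, where e(h) is the supporting-cluster extent — using
E = 0.5, H = 2, 26-connectivity, and midpoint numerical integration with
step dh = max/10 by default (the closed form for a flat cluster,
e^0.5·h³/3, is matched to < 0.5% at dh = h/1000). Positive and negative
excursions are enhanced separately. The FWE-corrected p of a voxel is the
fraction of permutations (identity included, n_perm random draws plus
identity) whose maximum enhanced statistic reaches the observed one, so
the smallest attainable p is 1/(n_perm+1). Max-statistic FWE is the
canonical pairing for TFCE permutation inference; a Benjamini–Hochberg
FDR alternative on per-voxel permutation p-values is computed alongside
because either correction convention may be wanted when reporting cluster
tables. Cluster tables report peak coordinate, peak t, minimum corrected
p, and size in voxels, mm³ and cc.

*Correlations.* Per (VOI, clinical score) pair, both variables are
screened with a Lilliefors normality test at 0.05; Pearson is used when
both pass, Spearman otherwise; significance is declared at p < 0.01.
Constant variables and pairs with fewer than 5 complete observations are
reported as NA with a reason.

*Individual flagging.* For a single subject, each VOI mean is compared to
the reference cohort's age-adjusted lower bound: linear regression of
uptake on age in the reference cohort, bound = prediction − 2 residual
sd. The 2-sd rule is a package convention for "below the normative
range"; reference cohorts smaller than 10 are rejected.

## Synthetic cohort generator

The generator emulates post-registration, reconstruction-free volumes; no
projection physics, attenuation or scatter are modeled. Geometry: two
ellipsoids per hemisphere (dorsal ≈ 2.4 cc, ventral ≈ 1.1 cc at the
default 64×64×48 grid / 2 mm voxels), mirrored at the midline, the dorsal
body superior-posterior to the ventral one, plus a large
posterior-inferior occipital reference ellipsoid. Regions must be mutually
disjoint and inside the grid; violations raise with the offending pair
named.

Signal model per subject:

* background `background_mean` (default 0) everywhere;
* group amplitude added inside each striatal ellipsoid — defaults
  (standardized-equivalent units): NMNC dorsal 4.5/4.6 (R/L), ventral
  3.5; NMC dorsal 4.2/4.3, ventral 3.4; PD dorsal 2.2/2.3, ventral 2.0 —
  i.e. PD strongly reduced everywhere and most dorsally, NMC mildly
  reduced with the right dorsal body leading;
* a per-subject, per-region amplitude offset ~ N(0, 0.5) (clipped at 0),
  giving between-subject VOI-mean spread of ≈ 0.5, the realistic order
  for group-level error bars in this design;
* background texture ~ N(0, √0.75) on non-striatal voxels and measurement
  noise ~ N(0, 0.5) everywhere, so the reference region has total unit sd
  and standardized uptake lands on the amplitude scale while in-region
  voxel noise stays at 0.5;
* optional Gaussian smoothing (FWHM in mm; default off — edge blurring
  would dilute the analytic calibration and is not needed for the
  pipeline's validation).

Ages are drawn per group (PD 63±9, NMC 48±11, NMNC 47±12 years) and
clinical scales (UPDRS-III, MoCA, UPSIT, BDI, SCOPA-AUT, ESS, RBDQ, NMS)
from group-conditional normals clipped to each scale's valid range —
independent of uptake given group, so the correlation screen runs under a
known null. All randomness flows from one seed through spawned
`SeedSequence` streams; identical configurations are bit-reproducible.

What the generator does *not* emulate: anatomical shape variability,
registration error, partial-volume effects at region borders, spatially
correlated noise, or caudate/putamen substructure. Passing tests therefore
demonstrate correctness of the analysis machinery and recoverability of
the designed effects, not robustness to real-scanner artifacts.

## Simulation scales

The test suite validates error control at desk scale: family-wise error
over 200 null cohorts of 16 subjects on 16×16×12 grids with 200
permutations each; ANCOVA null calibration over 500 simulated cohorts;
correlation type-I error over 1000 draws at n = 31; structure recovery
(k = 2 per hemisphere) over 20 full-size default cohorts; converter
flagging over 25 seeds. These sizes give binomial confidence intervals
tight enough to detect miscalibration while keeping the whole suite fast.

## Known limitations

* The dorsal/ventral semantic labeling assumes the dorsal cluster retains
  the higher pooled-mean uptake; in a cohort dominated by extreme dorsal
  denervation the rule could invert, which is why the centroid-height
  tie-break exists.
* Hemisphere naming trusts the declared grid orientation; flipped inputs
  would silently swap L/R.
* The permutation test covers two-group contrasts (run pairwise for three
  groups); no exchangeability blocks, variance smoothing, or longitudinal
  models.
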