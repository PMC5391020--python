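"""Group inference on standardized uptake.

Four analyses:

* **VOI comparison** — per VOI, an ordinary linear model
  ``uptake ~ group + age`` with pairwise group contrasts on adjusted means
  and Bonferroni correction across (VOIs x contrasts).
* **Voxel-wise permutation inference** — a two-group contrast inside the
  striatum mask, with nuisance covariates handled by the Freedman-Lane
  scheme and family-wise error control through the permutation distribution
  of the maximum TFCE-enhanced statistic (a Benjamini-Hochberg FDR
  alternative on per-voxel permutation p-values is also computed).
* **Clinical correlations** — per (VOI, score) pair, a Lilliefors
  normality check routes to Pearson (both normal) or Spearman.
* **Individual flagging** — a subject's VOI mean is compared against the
  age-adjusted lower bound of a reference cohort (regression prediction
  minus 2 residual sd), the single-subject analogue of the group tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class TFCEParams:
    """Threshold-free cluster enhancement settings.

    ``E`` and ``H`` are the extent and height exponents (standard 3D
    defaults 0.5 and 2.0); ``dh`` is the integration step — when ``None``
    it is set to one tenth of the map maximum, i.e. 10 integration steps.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[self.connectivity])


# --------------------------------------------------------------------------
# TFCE
# --------------------------------------------------------------------------

def _tfce_one_sign(stat: np.ndarray, mask: np.ndarray, params: TFCEParams) -> np.ndarray:
    """Enhance the positive excursions of ``stat`` within ``mask``."""
    out = np.zeros_like(stat, dtype=np.float64)
    clipped = np.where(mask, stat, 0.0)
    hmax = float(clipped.max(initial=0.0))
    if hmax <= 0:
        return out
    dh = params.dh if params.dh is not None else hmax / 10.0
    # midpoint rule: thresholds at (i - 1/2) dh strictly below the maximum
    thresholds = np.arange(dh / 2.0, hmax, dh)
    for h in thresholds:
        above = clipped >= h
        labeled, _ = ndimage.label(above, structure=params.structure)
        sizes = np.bincount(labeled.ravel()).astype(np.float64)
        sizes[0] = 0.0
        out[above] += (sizes[labeled[above]] ** params.E) * (h ** params.H) * dh
    return out


def tfce_enhance(
    stat_map: np.ndarray, mask: np.ndarray | None = None, params: TFCEParams = TFCEParams()
) -> np.ndarray:
    """TFCE: integrate supporting-cluster extent^E x height^H over heights.

    Positive and negative excursions are enhanced separately; the output
    keeps the sign of the input and is zero outside the mask.  An all-zero
    map enhances to an all-zero map.
    """
    stat = np.asarray(stat_map, dtype=np.float64)
    if not np.all(np.isfinite(stat)):
        raise ValueError("statistic map contains non-finite values")
    if mask is None:
        mask = np.ones(stat.shape, dtype=bool)
    mask = np.asarray(mask, bool)
    if mask.shape != stat.shape:
        raise ValueError("mask shape must match the statistic map")
    pos = _tfce_one_sign(stat, mask, params)
    neg = _tfce_one_sign(-stat, mask, params)
    return pos - neg


# --------------------------------------------------------------------------
# VOI-level ANCOVA-style comparison
# --------------------------------------------------------------------------

@dataclass
class VOIGroupResult:
    """Adjusted means and pairwise contrasts per VOI."""

    adjusted_means: pd.DataFrame  # VOIs x groups
    contrasts: pd.DataFrame  # voi, contrast, estimate, t, df, p_raw, p_bonf
    n_tests: int
    age_adjusted: bool


def _pairwise(groups: list[str]) -> list[tuple[str, str]]:
    return [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]


def voi_group_comparison(
    voi_means: pd.DataFrame,
    groups: pd.Series,
    ages: pd.Series | None = None,
    alpha: float = 0.05,
    expected_order: tuple[str, ...] | None = None,
) -> VOIGroupResult:
    """Linear model ``uptake ~ group + age`` per VOI with pairwise contrasts.

    ``expected_order`` lists group labels from lowest to highest expected
    uptake; when given, each contrast's p-value is one-sided in that
    direction (matching directional group hypotheses), otherwise two-sided.
    Bonferroni correction spans all VOIs x pairwise contrasts.
    """
    groups = pd.Series(groups).astype(str)
    group_names = sorted(groups.unique())
    if len(group_names) < 2:
        raise ValueError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts < 3).any():
        raise ValueError(f"every group needs >= 3 subjects, got {counts.to_dict()}")

    age_adjusted = ages is not None
    if ages is not None:
        ages = pd.Series(ages).astype(float)
        within_var = groups.groupby(groups).apply(lambda g: ages.loc[g.index].var())
        if ages.var() == 0 or np.allclose(within_var.fillna(0.0), 0.0):
            warnings.warn(
                "ages are constant within every group; dropping the age covariate",
                stacklevel=2,
            )
            ages = None
            age_adjusted = False

    n = len(groups)
    dummies = pd.get_dummies(groups)[group_names].to_numpy(dtype=float)
    X = dummies  # cell-means coding: one column per group
    if ages is not None:
        X = np.column_stack([X, ages.to_numpy() - ages.mean()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    pinv = np.linalg.pinv(X)
    XtX_inv = np.linalg.inv(X.T @ X)
    df = n - X.shape[1]

    pairs = _pairwise(group_names)
    order = {g: i for i, g in enumerate(expected_order)} if expected_order else None

    adj_rows = {}
    rows = []
    for voi in voi_means.columns:
        y = voi_means[voi].to_numpy(dtype=float)
        beta = pinv @ y
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / df
        # adjusted group means = cell means at the mean age (age centered)
        adj_rows[voi] = {g: float(beta[i]) for i, g in enumerate(group_names)}
        for a, b in pairs:
            c = np.zeros(X.shape[1])
            c[group_names.index(a)] = 1.0
            c[group_names.index(b)] = -1.0
            est = float(c @ beta)
            se = float(np.sqrt(sigma2 * (c @ XtX_inv @ c)))
            t = est / se if se > 0 else 0.0
            if order is not None and a in order and b in order:
                # one-sided in the expected direction (higher-ranked > lower)
                sign = 1.0 if order[a] > order[b] else -1.0
                p = float(sps.t.sf(sign * t, df))
            else:
                p = float(2.0 * sps.t.sf(abs(t), df))
            rows.append(
                {"voi": voi, "contrast": f"{a}-{b}", "estimate": est, "t": t, "df": df, "p_raw": p}
            )

    contrasts = pd.DataFrame(rows)
    m = len(contrasts)
    contrasts["p_bonf"] = np.minimum(1.0, contrasts["p_raw"] * m)
    contrasts["significant"] = contrasts["p_bonf"] < alpha
    adjusted = pd.DataFrame(adj_rows).T[group_names]
    adjusted.index.name = "voi"
    return VOIGroupResult(
        adjusted_means=adjusted, contrasts=contrasts, n_tests=m, age_adjusted=age_adjusted
    )


# --------------------------------------------------------------------------
# voxel-wise permutation inference
# --------------------------------------------------------------------------

@dataclass
class VoxelwiseResult:
    t_map: np.ndarray
    tfce_map: np.ndarray
    p_fwe_map: np.ndarray  # 1.0 outside the mask
    p_fdr_map: np.ndarray
    mask: np.ndarray
    n_perm: int
    max_null: np.ndarray  # permutation distribution of the max TFCE

    def cluster_table(
        self, alpha: float = 0.05, voxel_size=(2.0, 2.0, 2.0), use: str = "fwe"
    ) -> pd.DataFrame:
        """Connected clusters of corrected-significant voxels."""
        p = self.p_fwe_map if use == "fwe" else self.p_fdr_map
        sig = (p < alpha) & self.mask
        labeled, n = ndimage.label(sig, structure=ndimage.generate_binary_structure(3, 3))
        voxel_mm3 = float(np.prod(voxel_size))
        rows = []
        for c in range(1, n + 1):
            m = labeled == c
            tvals = np.where(m, self.t_map, -np.inf)
            peak = np.unravel_index(int(np.argmax(tvals)), tvals.shape)
            rows.append(
                {
                    "cluster": c,
                    "peak_x": peak[0],
                    "peak_y": peak[1],
                    "peak_z": peak[2],
                    "peak_t": float(self.t_map[peak]),
                    "min_p_corr": float(p[m].min()),
                    "n_voxels": int(m.sum()),
                    "size_mm3": float(m.sum() * voxel_mm3),
                    "size_cc": float(m.sum() * voxel_mm3 / 1000.0),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "cluster", "peak_x", "peak_y", "peak_z", "peak_t",
                "min_p_corr", "n_voxels", "size_mm3", "size_cc",
            ],
        )


def _t_maps(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """Vectorized OLS t-statistics for one contrast over many voxels."""
    pinv = np.linalg.pinv(X)
    XtX_inv = np.linalg.inv(X.T @ X)
    df = X.shape[0] - X.shape[1]
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    cvar = float(contrast @ XtX_inv @ contrast)
    se = np.sqrt(np.maximum(sigma2 * cvar, 1e-300))
    return (contrast @ beta) / se


def voxelwise_permutation_test(
    data: np.ndarray,
    group_labels,
    mask: np.ndarray,
    covariates: np.ndarray | None = None,
    contrast: tuple[str, str] | None = None,
    n_perm: int = 5000,
    params: TFCEParams = TFCEParams(),
    seed: int = 0,
) -> VoxelwiseResult:
    """One-sided two-group contrast with Freedman-Lane max-TFCE inference.

    ``data`` is (n_subjects, nx, ny, nz); ``contrast = (A, B)`` tests
    A > B (default: the two labels in sorted order).  Nuisance covariates
    are regressed out of the data, the reduced-model residuals are permuted
    and re-added to the nuisance fit, and the full-model t-map of each
    permuted dataset is TFCE-enhanced; the FWE-corrected p-value of a voxel
    is the fraction of permutations (identity included) whose maximum
    enhanced statistic reaches the observed one, so the smallest attainable
    p is 1/(n_perm + 1).
    """
    data = np.asarray(data, dtype=np.float64)
    mask = np.asarray(mask, bool)
    labels = pd.Series(group_labels).astype(str)
    if data.shape[0] != len(labels):
        raise ValueError("one volume per subject is required")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    uniq = sorted(labels.unique())
    if contrast is None:
        if len(uniq) != 2:
            raise ValueError("contrast must be given when more than two groups are present")
        contrast = (uniq[1], uniq[0]) if uniq[0] < uniq[1] else (uniq[0], uniq[1])
    a, b = contrast
    keep = labels.isin([a, b]).to_numpy()
    labels = labels[keep].reset_index(drop=True)
    Ydata = data[keep]
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError(f"each group needs >= 3 subjects, got {counts.to_dict()}")
    n = len(labels)

    g = (labels == a).to_numpy(dtype=float)
    Z = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov = cov[keep] if cov.shape[0] == len(keep) else cov
        if cov.shape[0] != n:
            raise ValueError("covariates must have one row per subject")
        if cov.shape[1] >= n:
            raise ValueError("more covariates than subjects")
        Z = np.column_stack([Z, cov - cov.mean(axis=0)])
    X = np.column_stack([g, Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    cvec = np.zeros(X.shape[1])
    cvec[0] = 1.0

    Y = Ydata[:, mask]  # (n, n_voxels)

    # Freedman-Lane: fit nuisance-only model, permute its residuals
    pinvZ = np.linalg.pinv(Z)
    fitted = Z @ (pinvZ @ Y)
    resid = Y - fitted

    def tfce_of(Yp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tv = _t_maps(Yp, X, cvec)
        tmap = np.zeros(mask.shape)
        tmap[mask] = tv
        enh = _tfce_one_sign(tmap, mask, params)
        return tv, enh[mask]

    t_obs, tfce_obs = tfce_of(Y)

    # n_perm random permutations plus the identity, so the smallest
    # attainable corrected p is 1 / (n_perm + 1)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm + 1)
    exceed_fwe = np.zeros(tfce_obs.shape)
    exceed_vox = np.zeros(tfce_obs.shape)
    for i in range(n_perm + 1):
        perm = np.arange(n) if i == 0 else rng.permutation(n)
        Yp = fitted + resid[perm]
        _, tfce_p = tfce_of(Yp)
        mx = float(tfce_p.max(initial=0.0))
        max_null[i] = mx
        exceed_fwe += mx >= tfce_obs
        exceed_vox += tfce_p >= tfce_obs

    p_fwe = exceed_fwe / (n_perm + 1)
    p_unc = exceed_vox / (n_perm + 1)
    _, p_fdr, _, _ = multipletests(p_unc, method="fdr_bh")

    t_map = np.zeros(mask.shape)
    t_map[mask] = t_obs
    tfce_map = np.zeros(mask.shape)
    tfce_map[mask] = tfce_obs
    p_fwe_map = np.ones(mask.shape)
    p_fwe_map[mask] = p_fwe
    p_fdr_map = np.ones(mask.shape)
    p_fdr_map[mask] = p_fdr
    return VoxelwiseResult(
        t_map=t_map,
        tfce_map=tfce_map,
        p_fwe_map=p_fwe_map,
        p_fdr_map=p_fdr_map,
        mask=mask,
        n_perm=n_perm,
        max_null=max_null,
    )


# --------------------------------------------------------------------------
# clinical correlations
# --------------------------------------------------------------------------

def correlate_voi_clinical(
    voi_means: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.01,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate each VOI's uptake with each clinical score.

    Both variables are screened with a Lilliefors (Kolmogorov-Smirnov with
    estimated parameters) normality test; Pearson is used when both pass at
    ``normality_alpha``, Spearman otherwise.  Constant variables yield an
    NA row with a reason.  Significance is declared at ``alpha`` (a strict
    0.01 by default, as befits a many-pair screen).
    """
    rows = []
    for voi in voi_means.columns:
        for score in clinical.columns:
            pair = pd.concat([voi_means[voi], clinical[score]], axis=1, join="inner").dropna()
            x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            base = {"voi": voi, "score": score, "n": len(pair)}
            if len(pair) < 5:
                rows.append({**base, "method": "NA", "r": np.nan, "p": np.nan,
                             "significant": False, "note": "fewer than 5 paired observations"})
                continue
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({**base, "method": "NA", "r": np.nan, "p": np.nan,
                             "significant": False, "note": "constant variable"})
                continue
            px = lilliefors(x, dist="norm")[1]
            py = lilliefors(y, dist="norm")[1]
            if px > normality_alpha and py > normality_alpha:
                r, p = sps.pearsonr(x, y)
                method = "pearson"
            else:
                r, p = sps.spearmanr(x, y)
                method = "spearman"
            rows.append({**base, "method": method, "r": float(r), "p": float(p),
                         "significant": bool(p < alpha), "note": ""})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# individual flagging
# --------------------------------------------------------------------------

def flag_individual(
    subject_voi_means: pd.Series,
    subject_age: float,
    reference_voi_means: pd.DataFrame,
    reference_ages: pd.Series,
    n_sd: float = 2.0,
) -> pd.DataFrame:
    """Flag VOIs where a subject falls below the reference normal range.

    Per VOI, uptake is regressed on age in the reference cohort; the lower
    bound at the subject's age is the prediction minus ``n_sd`` residual
    standard deviations.  A VOI is flagged "reduced" when the subject's
    mean lies below that bound.
    """
    ref_ages = pd.Series(reference_ages).astype(float)
    if len(reference_voi_means) < 10:
        raise ValueError(
            f"reference cohort too small ({len(reference_voi_means)} subjects; need >= 10)"
        )
    X = np.column_stack([np.ones(len(ref_ages)), ref_ages.to_numpy()])
    rows = []
    for voi in reference_voi_means.columns:
        y = reference_voi_means[voi].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        resid_sd = float(np.sqrt((resid @ resid) / (len(y) - 2)))
        predicted = float(beta[0] + beta[1] * subject_age)
        bound = predicted - n_sd * resid_sd
        value = float(subject_voi_means[voi])
        rows.append(
            {
                "voi": voi,
                "value": value,
                "predicted": predicted,
                "lower_bound": bound,
                "flagged": bool(value < bound),
            }
        )
    return pd.DataFrame(rows).set_index("voi")


def bonferroni(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Bonferroni correction: min(1, m * p)."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)
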