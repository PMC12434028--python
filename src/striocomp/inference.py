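"""Group-level statistics.

Covariate-adjusted comparisons of scalar measures (linear-model F tests with
Benjamini-Hochberg correction within pre-declared families) and voxelwise
nonparametric inference: Freedman-Lane permutation of reduced-model
residuals, t-maps with Gaussian-smoothed variance, threshold-free cluster
enhancement (TFCE), and family-wise error correction by the null
distribution of the permutation maximum.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .grid import Grid, connectivity_structure


# ---------------------------------------------------------------------------
# Design matrices and scalar comparisons
# ---------------------------------------------------------------------------


def build_design(table: pd.DataFrame,
                 covariates: tuple[str, ...] = ("study_id", "scanner_id", "age")) -> np.ndarray:
    """Covariates-of-no-interest design (intercept + expanded covariates).

    Categorical covariates are expanded to indicator columns; raises when the
    expanded design is rank deficient, naming the offending columns.
    """
    cols = [pd.Series(np.ones(len(table)), index=table.index, name="intercept")]
    for c in covariates:
        col = table[c]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            cols.extend(dummies[c2] for c2 in dummies)
        else:
            cols.append(col.astype(float))
    X = pd.concat(cols, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"design is rank deficient; check columns {list(X.columns)}")
    return X.to_numpy(dtype=float)


@dataclass
class GroupComparison:
    """Result of one covariate-adjusted group comparison."""

    outcome: str
    f_statistic: float
    p_value: float
    percent_difference: float  # of adjusted means, group vs reference
    direction: str             # "lower" | "higher" | "equal" (group vs reference)
    df_num: float
    df_den: float


def group_compare(table: pd.DataFrame, outcome: str, group_col: str = "group",
                  covariates: tuple[str, ...] = ("study_id", "scanner_id", "age"),
                  group_level: str = "MDD", reference_level: str = "HC") -> GroupComparison:
    """Linear-model F test of the group effect, adjusting for covariates.

    Returns the F statistic and p for the group indicator plus the percent
    difference of covariate-adjusted means (``group_level`` relative to
    ``reference_level``).
    """
    for col in (outcome, group_col, *covariates):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    counts = table[group_col].value_counts()
    if counts.get(group_level, 0) < 2 or counts.get(reference_level, 0) < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.isclose(table[outcome].std(ddof=1), 0.0):
        raise ValueError(f"outcome {outcome!r} is constant across subjects")
    df = table.copy()
    df["_y"] = df[outcome].astype(float)
    terms = []
    for c in covariates:
        if df[c].dtype.kind in "OUSb":
            terms.append(f"C({c})")
        else:
            terms.append(c)
    formula = "_y ~ C({}) {}".format(group_col, "".join(f"+ {t}" for t in terms))
    # rank check on the expanded design (statsmodels silently drops nothing)
    X = build_design(df, covariates)
    if len(df) - (X.shape[1] + 1) <= 0:
        raise ValueError("too few subjects for the covariate model "
                         "(zero residual degrees of freedom)")
    model = ols(formula, data=df).fit()
    table_anova = anova_lm(model, typ=2)
    row = table_anova.loc[f"C({group_col})"]
    # adjusted means: predict with every subject assigned to each group
    pred = {}
    for level in (group_level, reference_level):
        alt = df.copy()
        alt[group_col] = level
        pred[level] = float(model.predict(alt).mean())
    ref = pred[reference_level]
    pct = 100.0 * (pred[group_level] - ref) / ref if ref != 0 else math.nan
    direction = ("equal" if np.isclose(pred[group_level], ref)
                 else "lower" if pred[group_level] < ref else "higher")
    return GroupComparison(outcome, float(row["F"]), float(row["PR(>F)"]), pct,
                           direction, float(row["df"]),
                           float(table_anova.loc["Residual", "df"]))


@dataclass
class AssociationResult:
    """Covariate-adjusted linear association of an outcome with a regressor."""

    outcome: str
    regressor: str
    slope: float
    f_statistic: float
    p_value: float


def association_test(table: pd.DataFrame, outcome: str, regressor: str,
                     covariates: tuple[str, ...] = ("study_id", "scanner_id", "age")
                     ) -> AssociationResult:
    """F test of a continuous regressor (e.g. severity score), adjusting for
    covariates of no interest."""
    df = table.copy()
    df["_y"] = df[outcome].astype(float)
    df["_x"] = df[regressor].astype(float)
    if np.isclose(df["_y"].std(ddof=1), 0.0):
        raise ValueError(f"outcome {outcome!r} is constant across subjects")
    terms = [f"C({c})" if df[c].dtype.kind in "OUSb" else c for c in covariates]
    X = build_design(df, covariates)
    if len(df) - (X.shape[1] + 1) <= 0:
        raise ValueError("too few subjects for the covariate model "
                         "(zero residual degrees of freedom)")
    model = ols("_y ~ _x {}".format("".join(f"+ {t}" for t in terms)), data=df).fit()
    tab = anova_lm(model, typ=2)
    return AssociationResult(outcome, regressor, float(model.params["_x"]),
                             float(tab.loc["_x", "F"]), float(tab.loc["_x", "PR(>F)"]))


def bh_adjust(p_values, family: str = "", q: float = 0.05) -> pd.DataFrame:
    """Step-up Benjamini-Hochberg adjustment within one family of tests.

    Returns a table with the raw p, the adjusted p and the discovery flag at
    the given q.  BH controls the false discovery rate; the output column is
    named ``bh_adjusted`` so the procedure is unambiguous even when the
    correction is used in a family-wise role.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError(f"empty test family {family!r}")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame({"family": family, "p": p, "bh_adjusted": adj,
                         "discovery": reject})


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TFCEParams:
    """Threshold-free cluster enhancement parameters (H=2, E=0.5, 100 steps
    and 26-connectivity are the conventional neuroimaging defaults)."""

    height_exponent: float = 2.0
    extent_exponent: float = 0.5
    n_steps: int = 100
    dh: float | None = None  # overrides n_steps when given
    connectivity: int = 26

    def validate(self) -> None:
        if self.height_exponent < 0 or self.extent_exponent < 0:
            raise ValueError("TFCE exponents must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def tfce(stat_map: np.ndarray, mask: np.ndarray, params: TFCEParams | None = None,
         voxel_volume: float = 1.0) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic map.

    Per voxel, integrates extent(h)^E * h^H dh over thresholds h from 0 up
    to the voxel's statistic, where extent(h) is the volume of the
    suprathreshold connected component containing the voxel.  Negative
    statistics are enhanced on the negated map and returned with negative
    sign.
    """
    params = params or TFCEParams()
    params.validate()
    x = np.asarray(stat_map, dtype=float)
    if not np.isfinite(x[mask]).all():
        raise ValueError("statistic map contains non-finite values in the mask")
    out = _tfce_positive(np.where(mask, x, 0.0), mask, params, voxel_volume)
    neg = _tfce_positive(np.where(mask, -x, 0.0), mask, params, voxel_volume)
    return out - neg


def _tfce_positive(x: np.ndarray, mask: np.ndarray, params: TFCEParams,
                   voxel_volume: float) -> np.ndarray:
    top = float(x.max(initial=0.0))
    if top <= 0:
        return np.zeros_like(x)
    dh = params.dh if params.dh is not None else top / params.n_steps
    structure = connectivity_structure(params.connectivity)
    out = np.zeros_like(x)
    # midpoint thresholds (k - 1/2) * dh: strictly interior to (0, top), so
    # the topmost threshold never coincides with the map maximum and the
    # discretization is stable to rounding of the maximum itself
    k = 1
    while True:
        h = (k - 0.5) * dh
        if h >= top:
            break
        sup = (x >= h) & mask
        labels, n = ndimage.label(sup, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel()).astype(float) * voxel_volume
        contrib = (sizes ** params.extent_exponent) * (h ** params.height_exponent) * dh
        contrib[0] = 0.0
        out += contrib[labels]
        k += 1
    return out


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Voxelwise FWE-corrected permutation inference result."""

    grid: Grid
    mask: np.ndarray
    t_map: np.ndarray
    tfce_map: np.ndarray
    corrected_p: np.ndarray   # 1.0 outside the mask
    n_perm: int
    max_null: np.ndarray
    warnings: list[str] = field(default_factory=list)


def _t_maps(Y: np.ndarray, X: np.ndarray, contrast_col: int,
            smooth_sigma_vox: float, mask_idx, shape) -> np.ndarray:
    """Voxelwise t statistics for one design column, with the residual
    variance image optionally Gaussian-smoothed inside the mask."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    if smooth_sigma_vox > 0:
        vol = np.zeros(shape)
        w = np.zeros(shape)
        vol[mask_idx] = sigma2
        w[mask_idx] = 1.0
        vol = ndimage.gaussian_filter(vol, smooth_sigma_vox)
        w = ndimage.gaussian_filter(w, smooth_sigma_vox)
        sigma2 = (vol / np.maximum(w, 1e-12))[mask_idx]
    c = np.zeros(p)
    c[contrast_col] = 1.0
    var_scale = float(c @ np.linalg.inv(X.T @ X) @ c)
    se = np.sqrt(np.maximum(sigma2 * var_scale, 1e-300))
    return beta[contrast_col] / se


def permutation_test(subject_maps: np.ndarray, mask: np.ndarray,
                     regressor: np.ndarray, covariates: np.ndarray | None,
                     grid: Grid, n_perm: int = 5000,
                     variance_smoothing_mm: float = 2.0,
                     tfce_params: TFCEParams | None = None,
                     rng_seed: int = 0, exhaustive: bool = False) -> PermutationResult:
    """Voxelwise one-sided permutation test of a regressor of interest.

    ``subject_maps`` is (n_subjects, *grid.shape); ``regressor`` the effect
    of interest (e.g. a group indicator or a severity score); ``covariates``
    an optional (n_subjects, k) nuisance design (an intercept is always
    included).  Nuisance effects are handled by Freedman-Lane
    residualization: residuals of the reduced (nuisance-only) model are
    permuted, nuisance fits are added back, and the full-model t statistic
    is recomputed.  The observed (identity) permutation is included in the
    null, so corrected p-values are bounded below by 1/n_perm.  Variance
    smoothing is a Gaussian kernel of the stated sigma in mm applied to the
    residual-variance image.  Significance is assessed on the TFCE-enhanced
    t map against the null distribution of its permutation maximum.
    """
    tfce_params = tfce_params or TFCEParams()
    n = subject_maps.shape[0]
    if n < 8 and not exhaustive:
        raise ValueError("need at least 8 subjects")
    warnings_list = []
    if n_perm < 100 and not exhaustive:
        warnings_list.append(f"n_perm={n_perm} is below 100; p-values are coarse")
    x = np.asarray(regressor, dtype=float)
    if np.isclose(x.std(), 0.0):
        raise ValueError("contrast regressor is constant; effect not estimable")
    Z = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)])
    X = np.column_stack([x, Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("full design is rank deficient; contrast not estimable")
    mask_idx = np.nonzero(mask)
    Y = subject_maps[(slice(None),) + mask_idx]
    sigma_vox = variance_smoothing_mm / grid.voxel_size

    # Freedman-Lane pieces: reduced-model fit and residuals
    pinv_z = np.linalg.pinv(Z)
    fitted_reduced = Z @ (pinv_z @ Y)
    resid_reduced = Y - fitted_reduced

    def stat_for(Y_perm: np.ndarray) -> np.ndarray:
        t = _t_maps(Y_perm, X, 0, sigma_vox, mask_idx, grid.shape)
        t_vol = np.zeros(grid.shape)
        t_vol[mask_idx] = t
        enh = tfce(t_vol, mask, tfce_params, grid.voxel_volume)
        return enh[mask_idx]

    tfce_obs = stat_for(Y)
    if exhaustive:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
    else:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(rng_seed)))
        perms = [np.arange(n)] + [rng.permutation(n) for _ in range(n_perm - 1)]
    max_null = np.empty(len(perms))
    for i, perm in enumerate(perms):
        if i == 0 and not exhaustive:
            max_null[i] = tfce_obs.max(initial=0.0)
            continue
        Y_perm = fitted_reduced + resid_reduced[perm]
        max_null[i] = stat_for(Y_perm).max(initial=0.0)
    n_eff = len(perms)
    corr = (max_null[None, :] >= tfce_obs[:, None] - 1e-12).mean(axis=1)
    corrected = np.ones(grid.shape)
    corrected[mask_idx] = corr
    t_vol = np.zeros(grid.shape)
    t_vol[mask_idx] = _t_maps(Y, X, 0, sigma_vox, mask_idx, grid.shape)
    tfce_vol = np.zeros(grid.shape)
    tfce_vol[mask_idx] = tfce_obs
    return PermutationResult(grid, mask, t_vol, tfce_vol, corrected, n_eff,
                             max_null, warnings_list)


def cluster_descriptors(corrected_p: np.ndarray, mask: np.ndarray, grid: Grid,
                        alpha: float = 0.05, connectivity: int = 26) -> pd.DataFrame:
    """Significant clusters: center of gravity (world mm) and volume (mm^3),
    sorted by volume descending."""
    sig = (corrected_p < alpha) & mask
    labels, n = ndimage.label(sig, structure=connectivity_structure(connectivity))
    rows = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        cog = grid.world(vox).mean(axis=0)
        rows.append({"cog_x_mm": cog[0], "cog_y_mm": cog[1], "cog_z_mm": cog[2],
                     "volume_mm3": len(vox) * grid.voxel_volume,
                     "n_voxels": len(vox)})
    df = pd.DataFrame(rows, columns=["cog_x_mm", "cog_y_mm", "cog_z_mm",
                                     "volume_mm3", "n_voxels"])
    return df.sort_values("volume_mm3", ascending=False).reset_index(drop=True)
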