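"""ROI and voxelwise group statistics for boundary maps.

Covers the analysis battery applied to gwBZ/gwBTV values: three-group
ANCOVA with age and TIV as covariates and Bonferroni-corrected pairwise
post-hoc contrasts, partial and Pearson correlations, Benjamini-Hochberg
FDR with cluster-extent filtering of voxelwise maps, and logistic-regression
biomarker combination evaluated by ROC (AUC, DeLong p versus 0.5, and the
Youden-optimal sensitivity/specificity operating point).

Group "classification" of three diagnostic groups is carried out as three
pairwise binary problems (CN vs MCI, CN vs AD, MCI vs AD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage, stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .volio import ROIAtlas, Volume, check_common_space

__all__ = [
    "AncovaResult",
    "CorrelationResult",
    "RocResult",
    "VoxelStatMap",
    "ClusterMask",
    "roi_means",
    "ancova_group",
    "partial_corr",
    "pearson_corr",
    "bh_fdr",
    "voxel_glm",
    "cluster_threshold",
    "logistic_roc",
]


# --------------------------------------------------------------------------
# ROI summaries
# --------------------------------------------------------------------------

def roi_means(vol: Volume, atlas: ROIAtlas) -> dict[int, float]:
    """Mean of ``vol`` over each nonzero atlas label.

    Empty ROIs (labels in the name map without voxels) come back as NaN.
    """
    check_common_space([vol, atlas.labels])
    data = np.asarray(vol.data, dtype=np.float64)
    out: dict[int, float] = {}
    for lab in sorted(atlas.name_map):
        m = atlas.labels.data == lab
        n = int(m.sum())
        out[lab] = float(data[m].mean()) if n else float("nan")
    return out


# --------------------------------------------------------------------------
# ANCOVA
# --------------------------------------------------------------------------

@dataclass
class AncovaResult:
    """Group F-test from a linear model with continuous covariates.

    ``posthoc`` maps ordered group pairs to Bonferroni-adjusted p-values
    (raw p times the number of pairs, capped at 1), from pairwise contrasts
    within the full model.  ``adjusted_means`` are group means evaluated at
    the grand covariate means.
    """

    f: float
    p: float
    df: tuple[int, int]
    adjusted_means: dict[str, float]
    posthoc: dict[tuple[str, str], float]


def _design(groups: np.ndarray, order: list[str], covariates: np.ndarray) -> np.ndarray:
    n = len(groups)
    cols = [np.ones(n)]
    for g in order[1:]:
        cols.append((groups == g).astype(float))
    for j in range(covariates.shape[1]):
        cols.append(covariates[:, j])
    return np.column_stack(cols)


def ancova_group(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    group_order: list[str] | None = None,
) -> AncovaResult:
    """ANCOVA comparing group means of ``values`` adjusted for covariates.

    Model: y ~ intercept + (k-1) group indicators + covariates, fitted by
    OLS; the group effect is the partial F-test of the indicator block.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if group_order is None:
        group_order = list(dict.fromkeys(groups.tolist()))
    counts = {g: int((groups == g).sum()) for g in group_order}
    if any(c < 2 for c in counts.values()):
        raise ValueError(f"every group needs n >= 2, got {counts}")
    cov = (
        np.empty((len(y), 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if cov.shape[0] != len(y):
        cov = cov.T
    X = _design(groups, group_order, cov)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    k = len(group_order)
    full = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, np.delete(X, np.s_[1:k], axis=1)).fit()
    fstat, pval, df_num = full.compare_f_test(reduced)
    # a saturated covariate fit leaves RSS ~ 0 and the F ratio is float noise
    if not np.isfinite(fstat) or fstat < 0:
        fstat = 0.0
    df = (int(df_num), int(full.df_resid))

    cov_means = cov.mean(axis=0) if cov.size else np.empty(0)
    beta = full.params
    base = beta[0] + float(beta[k:] @ cov_means)
    adjusted = {group_order[0]: base}
    for i, g in enumerate(group_order[1:], start=1):
        adjusted[g] = base + beta[i]

    n_pairs = k * (k - 1) // 2
    posthoc: dict[tuple[str, str], float] = {}
    for a in range(k):
        for b in range(a + 1, k):
            c = np.zeros(X.shape[1])
            if a > 0:
                c[a] = -1.0
            if b > 0:
                c[b] = 1.0
            raw = float(full.t_test(c).pvalue)
            posthoc[(group_order[a], group_order[b])] = min(1.0, n_pairs * raw)
    return AncovaResult(float(fstat), float(pval), df, adjusted, posthoc)


# --------------------------------------------------------------------------
# Correlations
# --------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    p: float
    df: int
    kind: str
    valid: bool = True


def pearson_corr(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x) - 2, "pearson")


def partial_corr(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> CorrelationResult:
    """Partial correlation of x and y controlling for covariates.

    Both variables are residualized on [intercept + covariates] by least
    squares; r is the Pearson correlation of the residuals, tested with
    df = n - 2 - n_covariates.  With no covariates this reduces exactly to
    the plain Pearson correlation.  Constant residuals are flagged invalid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = (
        np.empty((len(x), 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if cov.shape[0] != len(x):
        cov = cov.T
    q = cov.shape[1]
    if len(x) <= 2 + q:
        raise ValueError(f"need n > {2 + q}")
    Z = np.column_stack([np.ones(len(x)), cov])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        return CorrelationResult(float("nan"), float("nan"), len(x) - 2 - q, "partial", False)
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = len(x) - 2 - q
    r_cl = min(max(r, -1.0), 1.0)
    if abs(r_cl) == 1.0:
        p = 0.0
    else:
        t = r_cl * np.sqrt(df / (1.0 - r_cl**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(r_cl, p, df, "partial")


# --------------------------------------------------------------------------
# Multiple testing and clusters
# --------------------------------------------------------------------------

def bh_fdr(pvals: np.ndarray, alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj = multipletests(p, alpha=alpha, method="fdr_bh")[:2]
    return reject, adj


@dataclass
class ClusterMask:
    """Connected components surviving the cluster-extent threshold."""

    mask: np.ndarray
    labels: np.ndarray
    table: pd.DataFrame  # columns: cluster_id, size, peak_x/y/z, peak_stat
    connectivity: int
    min_extent: int


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def cluster_threshold(
    mask: np.ndarray,
    min_extent: int = 100,
    connectivity: int = 18,
    stat: np.ndarray | None = None,
) -> ClusterMask:
    """Remove supra-threshold components smaller than ``min_extent`` voxels.

    Components are found under the given neighbourhood connectivity
    (6 faces, 18 faces+edges, 26 faces+edges+corners).  The cluster table is
    sorted by size descending; peaks come from ``stat`` when provided,
    otherwise the first voxel in scan order.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    rows = []
    keep = np.zeros_like(lab)
    next_id = 0
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = np.argsort(-sizes, kind="stable")
    for j in order:
        size = int(sizes[j])
        if size < min_extent:
            continue
        next_id += 1
        comp = lab == (j + 1)
        keep[comp] = next_id
        if stat is not None:
            s = np.where(comp, stat, -np.inf)
            peak = np.unravel_index(int(np.argmax(s)), s.shape)
            peak_stat = float(stat[peak])
        else:
            peak = tuple(int(c[0]) for c in np.nonzero(comp))
            peak_stat = float("nan")
        rows.append(
            {
                "cluster_id": next_id,
                "size": size,
                "peak_x": peak[0],
                "peak_y": peak[1],
                "peak_z": peak[2],
                "peak_stat": peak_stat,
            }
        )
    table = pd.DataFrame(
        rows, columns=["cluster_id", "size", "peak_x", "peak_y", "peak_z", "peak_stat"]
    )
    return ClusterMask(keep > 0, keep, table, connectivity, min_extent)


# --------------------------------------------------------------------------
# Voxelwise GLM
# --------------------------------------------------------------------------

@dataclass
class VoxelStatMap:
    """Voxelwise statistic and p-value grids over an analysis mask."""

    stat: Volume
    p: Volume
    mask: np.ndarray
    kind: str  # "F" or "T"
    df: tuple[int, int] | int


def voxel_glm(
    maps: list[Volume],
    design: pd.DataFrame,
    test_cols: list[str],
    mask: np.ndarray | None = None,
) -> VoxelStatMap:
    """Massively univariate least-squares fit of one design at every voxel.

    ``design`` must contain an ``intercept`` column (added if absent).  The
    effect of interest is the column block ``test_cols``: a partial F-test
    when it has more than one column (group ANCOVA), a two-sided t-test of
    the slope when it has exactly one (multiple regression).
    """
    if not maps:
        raise ValueError("no maps")
    check_common_space(maps)
    X = design.copy()
    if "intercept" not in X.columns:
        X.insert(0, "intercept", 1.0)
    if len(X) != len(maps):
        raise ValueError("design rows and maps misaligned")
    missing = [c for c in test_cols if c not in X.columns]
    if missing:
        raise ValueError(f"test columns not in design: {missing}")
    Xf = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if mask is None:
        mask = np.ones(maps[0].shape, dtype=bool)
    Y = np.stack([np.asarray(m.data, dtype=np.float64)[mask] for m in maps])  # (n, V)

    n, p_full = Xf.shape
    beta, *_ = np.linalg.lstsq(Xf, Y, rcond=None)
    rss_full = ((Y - Xf @ beta) ** 2).sum(axis=0)
    df_resid = n - p_full

    stat_grid = np.zeros(maps[0].shape)
    p_grid = np.ones(maps[0].shape)
    if len(test_cols) > 1:
        Xr = X.drop(columns=test_cols).to_numpy(dtype=float)
        beta_r, *_ = np.linalg.lstsq(Xr, Y, rcond=None)
        rss_red = ((Y - Xr @ beta_r) ** 2).sum(axis=0)
        q = len(test_cols)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss_red - rss_full) / q) / (rss_full / df_resid)
        f = np.where(np.isfinite(f), np.maximum(f, 0.0), 0.0)
        pv = stats.f.sf(f, q, df_resid)
        stat_grid[mask] = f
        p_grid[mask] = pv
        kind, df = "F", (q, df_resid)
    else:
        j = list(X.columns).index(test_cols[0])
        xtx_inv = np.linalg.inv(Xf.T @ Xf)
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma2 = rss_full / df_resid
            se = np.sqrt(sigma2 * xtx_inv[j, j])
            t = beta[j] / se
        t = np.where(np.isfinite(t), t, 0.0)
        pv = 2.0 * stats.t.sf(np.abs(t), df_resid)
        stat_grid[mask] = t
        p_grid[mask] = pv
        kind, df = "T", df_resid
    ref = maps[0]
    return VoxelStatMap(ref.like(stat_grid), ref.like(p_grid), mask, kind, df)


def fdr_cluster_filter(
    statmap: VoxelStatMap,
    alpha: float = 0.01,
    min_extent: int = 100,
    connectivity: int = 18,
) -> ClusterMask:
    """BH-FDR over the analysis mask, then cluster-extent filtering.

    The FDR rank is computed over in-mask voxels only, so background voxels
    never dilute the correction.
    """
    reject, _ = bh_fdr(statmap.p.data[statmap.mask], alpha=alpha)
    sig = np.zeros(statmap.p.shape, dtype=bool)
    sig[statmap.mask] = reject
    return cluster_threshold(
        sig, min_extent=min_extent, connectivity=connectivity, stat=statmap.stat.data
    )


# --------------------------------------------------------------------------
# Logistic regression + ROC
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    sensitivity: float  # percent, at the Youden-optimal threshold
    specificity: float  # percent
    p: float  # DeLong test of AUC vs 0.5
    threshold: float
    coef: np.ndarray | None = None
    separable: bool = False


def _delong_se(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong standard error of a single AUC via placement values."""
    m, n = len(pos), len(neg)
    cmp_mat = (pos[:, None] > neg[None, :]).astype(float)
    cmp_mat += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_mat.mean(axis=1)
    v01 = cmp_mat.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def logistic_roc(features: np.ndarray, labels: np.ndarray) -> RocResult:
    """Unpenalized logistic fit of one or more features, evaluated by ROC.

    Predicted probabilities are scored against the binary labels: AUC by
    trapezoid over all thresholds (equal to the tie-corrected Mann-Whitney
    statistic), sensitivity/specificity in percent at the Youden-J-maximizing
    threshold (ties broken toward the lowest threshold), and a DeLong test
    of AUC = 0.5.  Perfectly separable data is flagged; probabilities (and
    hence the AUC, which is invariant to monotone transforms) are still
    returned from the final iterate.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] != len(labels):
        X = X.T
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    y01 = (y == classes[1]).astype(float)

    Xc = sm.add_constant(X, has_constant="add")
    separable = False
    coef = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y01, Xc).fit(disp=0, maxiter=100, tol=1e-8)
            prob = np.asarray(fit.predict(Xc))
            coef = np.asarray(fit.params)
            if not fit.mle_retvals.get("converged", True):
                separable = True
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separable = True
            try:
                fit = sm.Logit(y01, Xc).fit(method="bfgs", disp=0, maxiter=500)
                prob = np.asarray(fit.predict(Xc))
                coef = np.asarray(fit.params)
            except Exception:
                # last resort: rank the single best separating direction
                prob = (X - X.mean(0)) @ np.linalg.pinv(X.std(0, ddof=0).reshape(-1, 1)).ravel()
                prob = stats.rankdata(prob) / (len(prob) + 1.0)

    if np.ptp(prob) == 0:
        # no information: flat scores
        return RocResult(0.5, 100.0, 0.0, 1.0, float(prob[0]), coef, separable)

    fpr, tpr, thr = roc_curve(y01, prob)
    auc_val = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.where(j == j.max())[0][-1])  # thresholds descend: last max = lowest
    sens = float(tpr[best] * 100.0)
    spec = float((1.0 - fpr[best]) * 100.0)

    pos = prob[y01 == 1]
    neg = prob[y01 == 0]
    se = _delong_se(pos, neg, auc_val)
    if se == 0:
        p = 0.0 if auc_val != 0.5 else 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(auc_val - 0.5) / se))
    if auc_val == 1.0:
        separable = True
    return RocResult(auc_val, sens, spec, p, float(thr[best]), coef, separable)
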