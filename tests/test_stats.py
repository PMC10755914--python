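"""ROI/voxel group statistics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gwboundary.stats import (
    ancova_group,
    bh_fdr,
    cluster_threshold,
    fdr_cluster_filter,
    logistic_roc,
    partial_corr,
    pearson_corr,
    roi_means,
    voxel_glm,
)
from gwboundary.volio import ROIAtlas, Volume


# ---------------------------------------------------------------------------
# ROI means
# ---------------------------------------------------------------------------

def _atlas_from(labels):
    labels = np.asarray(labels, dtype=np.int16)
    names = {int(l): f"roi{l}" for l in np.unique(labels) if l != 0}
    return ROIAtlas(Volume(labels), names)


def test_roi_means_basic_and_oracle():
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 4, size=(6, 6, 6))
    atlas = _atlas_from(labels)

    const = Volume(np.full((6, 6, 6), 0.3))
    assert all(v == pytest.approx(0.3) for v in roi_means(const, atlas).values())

    vals = Volume(rng.normal(size=(6, 6, 6)))
    got = roi_means(vals, atlas)
    for lab in (1, 2, 3):
        acc = [vals.data[idx] for idx in np.ndindex(vals.shape) if labels[idx] == lab]
        assert got[lab] == pytest.approx(np.mean(acc), abs=1e-12)


def test_roi_mean_of_symmetric_pair_is_zero():
    labels = np.zeros((2, 1, 1), dtype=np.int16)
    labels[:, 0, 0] = 1
    data = np.array([-1.0, 1.0]).reshape(2, 1, 1)
    assert roi_means(Volume(data), _atlas_from(labels))[1] == 0.0


def test_roi_means_flags_empty_roi():
    labels = np.ones((2, 2, 2), dtype=np.int16)
    atlas = ROIAtlas(Volume(labels), {1: "a", 2: "ghost"})
    out = roi_means(Volume(np.ones((2, 2, 2))), atlas)
    assert np.isnan(out[2])


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

def _fake_roi_data(n_per=20, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    groups = np.repeat(["CN", "MCI", "AD"], n_per)
    age = rng.normal(72, 5, size=3 * n_per)
    tiv = rng.normal(1350, 110, size=3 * n_per)
    y = rng.normal(0, 1, size=3 * n_per)
    y += effect * (groups == "AD")
    return y, groups, np.column_stack([age, tiv])


def test_ancova_covariate_absorbs_all_variance():
    rng = np.random.default_rng(1)
    groups = np.repeat(["CN", "MCI", "AD"], 10)
    age = rng.normal(70, 5, size=30)
    res = ancova_group(age.copy(), groups, age.reshape(-1, 1))
    assert res.f == 0.0
    assert res.p > 0.99


def test_ancova_matches_rss_ratio_oracle():
    y, groups, cov = _fake_roi_data(n_per=3, seed=2, effect=1.0)  # 9 subjects
    res = ancova_group(y, groups, cov, group_order=["CN", "MCI", "AD"])
    # oracle: explicit least squares of full vs group-dropped design
    d_mci = (groups == "MCI").astype(float)
    d_ad = (groups == "AD").astype(float)
    Xf = np.column_stack([np.ones(len(y)), d_mci, d_ad, cov])
    Xr = np.column_stack([np.ones(len(y)), cov])
    rss_f = np.sum((y - Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]) ** 2)
    rss_r = np.sum((y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]) ** 2)
    df2 = len(y) - Xf.shape[1]
    f_oracle = ((rss_r - rss_f) / 2) / (rss_f / df2)
    assert res.f == pytest.approx(f_oracle, abs=1e-10)
    assert res.df == (2, df2)
    assert res.p == pytest.approx(sps.f.sf(f_oracle, 2, df2), abs=1e-12)
    # post-hoc: Bonferroni x3 capped at 1
    assert all(0 <= p <= 1 for p in res.posthoc.values())
    assert set(res.posthoc) == {("CN", "MCI"), ("CN", "AD"), ("MCI", "AD")}


def test_ancova_f_invariant_to_covariate_rescaling():
    y, groups, cov = _fake_roi_data(n_per=15, seed=3, effect=0.5)
    res1 = ancova_group(y, groups, cov)
    res2 = ancova_group(y, groups, cov * np.array([100.0, 0.001]) + np.array([5.0, -2.0]))
    assert res1.f == pytest.approx(res2.f, abs=1e-9)


def test_ancova_contract_errors():
    y, groups, cov = _fake_roi_data(n_per=5, seed=4)
    with pytest.raises(ValueError, match="rank deficient"):
        ancova_group(y, groups, np.column_stack([cov[:, 0], cov[:, 0] * 2.0]))
    with pytest.raises(ValueError, match="n >= 2"):
        ancova_group(y[:11], groups[:11], cov[:11])  # AD group has a single subject


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def test_partial_corr_reduces_to_pearson_without_covariates():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=50), rng.normal(size=50)
    pc = partial_corr(x, y)
    pr = pearson_corr(x, y)
    assert pc.r == pytest.approx(pr.r, abs=1e-12)
    assert pc.p == pytest.approx(pr.p, abs=1e-12)


def test_partial_corr_removes_shared_covariate():
    rng = np.random.default_rng(6)
    x = rng.normal(size=200)
    age = rng.normal(size=200)
    y = x + age
    res = partial_corr(x, y, age.reshape(-1, 1))
    assert res.r > 0.95
    assert res.df == 200 - 3


def test_partial_corr_sign_and_degenerate():
    rng = np.random.default_rng(7)
    x = rng.normal(size=30)
    x = (x - x.mean()) / x.std()
    cov = rng.normal(size=(30, 1))
    cov -= cov.mean()
    res = partial_corr(x, -x, cov - cov * 0)  # covariate noise orthogonalized by residualization
    assert res.r == pytest.approx(-1.0, abs=1e-10)

    flagged = partial_corr(x, cov[:, 0].copy(), cov)  # y is exactly the covariate
    assert not flagged.valid


def test_partial_corr_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(8)
    df = pd.DataFrame(
        {
            "x": rng.normal(size=60),
            "y": rng.normal(size=60),
            "c1": rng.normal(size=60),
            "c2": rng.normal(size=60),
        }
    )
    df["y"] += 0.5 * df["x"] + 0.8 * df["c1"]
    ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
    res = partial_corr(df["x"].to_numpy(), df["y"].to_numpy(), df[["c1", "c2"]].to_numpy())
    assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)


def test_pearson_examples():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson_corr(x, 2 * x + 1).r == pytest.approx(1.0)

    rng = np.random.default_rng(9)
    big = rng.normal(size=1000)
    shuffled = rng.permutation(big)
    assert abs(pearson_corr(big, shuffled).r) < 0.1

    y = np.array([2.0, 1.0, 4.0, 3.0])
    r_formula = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert pearson_corr(x, y).r == pytest.approx(r_formula, abs=1e-12)

    with pytest.raises(ValueError, match="constant"):
        pearson_corr(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def _bh_oracle(p, alpha):
    """Exhaustive scan of all k thresholds p_(k) <= k*alpha/m."""
    m = len(p)
    order = np.argsort(p)
    ps = p[order]
    kmax = 0
    for k in range(1, m + 1):
        if ps[k - 1] <= k * alpha / m:
            kmax = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:kmax]] = True
    return reject


def test_bh_fdr_trivial_cases():
    rej, adj = bh_fdr(np.zeros(5), alpha=0.01)
    assert rej.all() and np.all(adj == 0)
    rej, adj = bh_fdr(np.array([0.03]), alpha=0.05)
    assert rej[0] and adj[0] == pytest.approx(0.03)
    with pytest.raises(ValueError):
        bh_fdr(np.array([0.5, 1.2]))


def test_bh_fdr_matches_exhaustive_threshold_oracle():
    rng = np.random.default_rng(10)
    p = np.concatenate([rng.uniform(0, 0.01, 10), rng.uniform(0, 1, 40)])
    for alpha in (0.01, 0.05):
        rej, _ = bh_fdr(p, alpha=alpha)
        np.testing.assert_array_equal(rej, _bh_oracle(p, alpha))
    # rejections nest across alpha levels
    r01, _ = bh_fdr(p, 0.01)
    r05, _ = bh_fdr(p, 0.05)
    assert np.all(r05[r01])


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def test_cluster_extent_boundary_of_rule():
    mask = np.zeros((10, 10, 10), dtype=bool)
    mask.flat[:0] = True
    blob = np.zeros((10, 10, 10), dtype=bool)
    blob[:4, :5, :5] = True  # 100 voxels
    res = cluster_threshold(blob, min_extent=100)
    assert res.mask.sum() == 100
    blob[0, 0, 0] = False  # 99 voxels
    res = cluster_threshold(blob, min_extent=100)
    assert res.mask.sum() == 0
    assert res.table.empty


def test_connectivity_corner_case():
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[0, 0, 0] = True
    mask[1, 1, 1] = True  # shares only a corner: 26-neighbour, not 18
    res18 = cluster_threshold(mask, min_extent=1, connectivity=18)
    assert len(res18.table) == 2
    res26 = cluster_threshold(mask, min_extent=1, connectivity=26)
    assert len(res26.table) == 1
    # edge-sharing voxels are 18-connected
    mask2 = np.zeros((4, 4, 4), dtype=bool)
    mask2[0, 0, 0] = True
    mask2[0, 1, 1] = True
    assert len(cluster_threshold(mask2, min_extent=1, connectivity=18).table) == 1
    assert len(cluster_threshold(mask2, min_extent=1, connectivity=6).table) == 2


def _bfs_components(mask, conn):
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
        and {6: abs(i) + abs(j) + abs(k) == 1, 18: abs(i) + abs(j) + abs(k) <= 2, 26: True}[conn]
    ]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue, comp = [start], set()
        seen[start] = True
        while queue:
            cur = queue.pop()
            comp.add(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= c < s for c, s in zip(nb, mask.shape)) and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        comps.append(comp)
    return comps


@pytest.mark.parametrize("conn", [6, 18, 26])
def test_cluster_labels_match_bfs_oracle(conn):
    rng = np.random.default_rng(11)
    mask = rng.random((8, 8, 8)) < 0.2
    res = cluster_threshold(mask, min_extent=1, connectivity=conn)
    oracle = _bfs_components(mask, conn)
    got = {
        frozenset((int(a), int(b), int(c)) for a, b, c in zip(*np.nonzero(res.labels == cid)))
        for cid in res.table["cluster_id"]
    }
    expect = {frozenset((int(a), int(b), int(c)) for a, b, c in comp) for comp in oracle}
    assert got == expect
    assert list(res.table["size"]) == sorted(res.table["size"], reverse=True)


# ---------------------------------------------------------------------------
# voxel GLM
# ---------------------------------------------------------------------------

def _voxel_dataset(n=30, shape=(5, 5, 5), seed=12, effect=0.0, roi=None):
    rng = np.random.default_rng(seed)
    groups = np.repeat(["CN", "MCI", "AD"], n // 3)
    design = pd.DataFrame(
        {
            "mci": (groups == "MCI").astype(float),
            "ad": (groups == "AD").astype(float),
            "age": rng.normal(72, 5, n),
            "tiv": rng.normal(1350, 110, n),
        }
    )
    maps = []
    for i in range(n):
        grid = rng.normal(size=shape)
        if effect and groups[i] == "AD":
            grid[roi] += effect
        maps.append(Volume(grid))
    return maps, design, groups


def test_voxel_glm_single_voxel_equals_scalar_oracles():
    maps, design, groups = _voxel_dataset()
    cov = design[["age", "tiv"]].to_numpy()
    fmap = voxel_glm(maps, design, ["mci", "ad"])
    tmap = voxel_glm(maps, design, ["age"])
    idx = (2, 3, 1)
    y = np.array([m.data[idx] for m in maps])
    scalar = ancova_group(y, groups, cov, group_order=["CN", "MCI", "AD"])
    assert fmap.stat.data[idx] == pytest.approx(scalar.f, abs=1e-10)
    assert fmap.p.data[idx] == pytest.approx(scalar.p, abs=1e-10)
    # t-test of the age slope via statsmodels on that voxel
    import statsmodels.api as sm

    X = sm.add_constant(design.to_numpy())
    fit = sm.OLS(y, X).fit()
    assert tmap.stat.data[idx] == pytest.approx(fit.tvalues[3], abs=1e-10)
    assert tmap.p.data[idx] == pytest.approx(fit.pvalues[3], abs=1e-10)


def test_voxel_glm_null_pvalues_uniform():
    maps, design, _ = _voxel_dataset(n=36, shape=(10, 10, 5), seed=13)
    fmap = voxel_glm(maps, design, ["mci", "ad"])
    pvals = fmap.p.data.ravel()
    assert len(pvals) == 500
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_voxel_glm_design_contracts():
    maps, design, _ = _voxel_dataset(n=12)
    with pytest.raises(ValueError, match="misaligned"):
        voxel_glm(maps[:-1], design, ["mci"])
    with pytest.raises(ValueError, match="not in design"):
        voxel_glm(maps, design, ["nope"])
    bad = design.copy()
    bad["dup"] = bad["age"]
    with pytest.raises(ValueError, match="rank deficient"):
        voxel_glm(maps, bad, ["mci", "ad"])


def test_planted_group_effect_recovered_inside_roi():
    roi = np.zeros((8, 8, 8), dtype=bool)
    roi[2:6, 2:6, 2:6] = True
    maps, design, _ = _voxel_dataset(n=30, shape=(8, 8, 8), seed=14, effect=3.0, roi=roi)
    fmap = voxel_glm(maps, design, ["mci", "ad"])
    clusters = fdr_cluster_filter(fmap, alpha=0.01, min_extent=10)
    assert clusters.mask.sum() > 0
    assert (clusters.mask & roi).sum() / clusters.mask.sum() >= 0.9


# ---------------------------------------------------------------------------
# logistic + ROC
# ---------------------------------------------------------------------------

def _auc_pair_count(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def test_roc_perfect_separation():
    x = np.concatenate([np.zeros(10), np.ones(10)])
    y = np.concatenate([np.zeros(10, int), np.ones(10, int)])
    res = logistic_roc(x.reshape(-1, 1), y)
    assert res.auc == pytest.approx(1.0)
    assert res.sensitivity == pytest.approx(100.0)
    assert res.specificity == pytest.approx(100.0)
    assert res.separable


def test_roc_uninformative_feature():
    x = np.full(20, 3.0)
    y = np.concatenate([np.zeros(10, int), np.ones(10, int)])
    res = logistic_roc(x.reshape(-1, 1), y)
    assert res.auc == pytest.approx(0.5)


def test_single_feature_auc_equals_pair_count_oracle():
    rng = np.random.default_rng(15)
    x = np.round(rng.normal(size=60), 1)  # rounding creates ties
    y = (rng.random(60) < 0.4).astype(int)
    res = logistic_roc(x.reshape(-1, 1), y)
    # the logistic probability of one feature is strictly monotone in the
    # feature (increasing or decreasing with the slope sign), so the model
    # AUC equals the raw-feature pair count up to direction
    raw = _auc_pair_count(x, y)
    assert res.auc == pytest.approx(max(raw, 1.0 - raw), abs=1e-12)
    # and the trapezoid AUC equals the pair-count oracle on the fitted scores
    prob = 1.0 / (1.0 + np.exp(-(res.coef[0] + res.coef[1] * x)))
    assert res.auc == pytest.approx(_auc_pair_count(prob, y), abs=1e-12)


def test_auc_invariant_to_monotone_transform():
    rng = np.random.default_rng(16)
    x = rng.normal(size=80)
    y = (x + rng.normal(size=80) > 0).astype(int)
    a1 = logistic_roc(x.reshape(-1, 1), y).auc
    a2 = logistic_roc(np.exp(2.0 * x).reshape(-1, 1), y).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_binormal_auc_closed_form():
    rng = np.random.default_rng(17)
    d = 1.0
    x = np.concatenate([rng.normal(0, 1, 200), rng.normal(d, 1, 200)])
    y = np.repeat([0, 1], 200)
    res = logistic_roc(x.reshape(-1, 1), y)
    assert res.auc == pytest.approx(sps.norm.cdf(d / np.sqrt(2)), abs=0.03)
    assert res.p < 0.001  # clearly better than chance by the DeLong test


def test_roc_contract_errors():
    with pytest.raises(ValueError, match="2 classes"):
        logistic_roc(np.arange(5.0).reshape(-1, 1), np.zeros(5, int))
    with pytest.raises(ValueError, match="non-finite"):
        logistic_roc(np.array([[np.nan], [1.0]]), np.array([0, 1]))
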