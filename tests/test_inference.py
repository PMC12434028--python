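import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_stepup, brute_tfce, exhaustive_freedman_lane

from striocomp import TFCEParams, bh_adjust, cluster_descriptors, group_compare, \
    permutation_test, tfce, association_test
from striocomp.grid import Grid
from striocomp.inference import build_design


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pvals,expected", [
    ([0.03], [0.03]),
    ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
    ([0.05, 0.5], [0.10, 0.50]),
])
def test_bh_hand_computed_examples(pvals, expected):
    out = bh_adjust(pvals, "family")
    assert np.allclose(out["bh_adjusted"], expected)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
def test_bh_matches_stepup_recipe_and_is_idempotent(pvals):
    adj = bh_adjust(pvals, "f")["bh_adjusted"].to_numpy()
    assert np.allclose(adj, bh_stepup(pvals))
    # adjusted values are monotone in raw-p order
    order = np.argsort(pvals, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_bh_empty_family_rejected():
    with pytest.raises(ValueError, match="empty"):
        bh_adjust([], "f")


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

def test_tfce_zero_and_uniform_maps():
    grid_mask = np.ones((3, 3, 3), bool)
    assert not tfce(np.zeros((3, 3, 3)), grid_mask).any()
    uniform = np.full((3, 3, 3), 2.0)
    out = tfce(uniform, grid_mask)
    assert np.allclose(out[grid_mask], out[1, 1, 1])
    assert out[1, 1, 1] > 0


def test_tfce_matches_brute_force_on_toy_map():
    mask = np.zeros((3, 1, 1), bool)
    mask[:, 0, 0] = True
    stat = np.zeros((3, 1, 1))
    stat[:, 0, 0] = [1.0, 2.0, 1.0]
    params = TFCEParams(height_exponent=2.0, extent_exponent=0.5, dh=0.01)
    mine = tfce(stat, mask, params)
    brute = brute_tfce(stat, mask, 2.0, 0.5, 0.01)
    assert mine[1, 0, 0] == pytest.approx(brute[1, 0, 0], abs=1e-3)
    assert np.allclose(mine[mask], brute[mask], atol=1e-3)


def test_tfce_positivity_and_monotonicity():
    rng = np.random.default_rng(3)
    mask = np.ones((5, 5, 4), bool)
    a = rng.random((5, 5, 4))
    b = a + rng.random((5, 5, 4)) * 0.5  # pointwise larger
    params = TFCEParams(dh=0.02)
    ea, eb = tfce(a, mask, params), tfce(b, mask, params)
    assert (ea[mask] >= 0).all()
    assert (eb[mask] >= ea[mask] - 1e-9).all()


def test_tfce_negative_values_enhanced_separately():
    mask = np.ones((4, 1, 1), bool)
    stat = np.zeros((4, 1, 1))
    stat[:, 0, 0] = [1.0, 1.0, -1.0, -1.0]
    out = tfce(stat, mask, TFCEParams(dh=0.05))
    assert out[0, 0, 0] > 0 and out[2, 0, 0] < 0
    assert out[0, 0, 0] == pytest.approx(-out[2, 0, 0])


def test_tfce_rejects_nonfinite():
    mask = np.ones((2, 2, 2), bool)
    bad = np.full((2, 2, 2), np.nan)
    with pytest.raises(ValueError, match="non-finite"):
        tfce(bad, mask)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _table(y_mdd, y_hc):
    n = len(y_mdd) + len(y_hc)
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "group": ["MDD"] * len(y_mdd) + ["HC"] * len(y_hc),
        "y": list(y_mdd) + list(y_hc),
        "study_id": (["a", "b"] * n)[:n],
        "scanner_id": (["s1", "s1", "s2", "s2"] * n)[:n],
        "age": rng.uniform(20, 40, n),
    })


def test_identical_groups_show_no_effect():
    vals = [1.0, 2.0, 3.0, 4.0]
    t = _table(vals, vals)
    res = group_compare(t, "y", covariates=("study_id",))
    assert res.percent_difference == pytest.approx(0.0, abs=1e-8)
    assert res.p_value > 0.99


def test_group_difference_direction_and_significance():
    rng = np.random.default_rng(1)
    t = _table(10 + rng.normal(0, 0.5, 12), 12 + rng.normal(0, 0.5, 12))
    res = group_compare(t, "y")
    assert res.direction == "lower" and res.p_value < 1e-4
    assert res.percent_difference < 0


def test_degenerate_inputs_rejected():
    t = _table([1.0] * 4, [1.0] * 4)
    with pytest.raises(ValueError, match="constant"):
        group_compare(t, "y")
    t2 = _table([1.0, 2.0], [1.0, 2.0, 3.0, 4.0])
    t2.loc[t2.index[:2], "group"] = "MDD"
    with pytest.raises(ValueError, match="2 subjects"):
        group_compare(_table([1.0], [1.0, 2.0]), "y")
    # collinear covariates are named
    t3 = _table([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.5])
    t3["age2"] = t3["age"]
    with pytest.raises(ValueError, match="rank deficient"):
        build_design(t3, ("age", "age2"))
    # a saturated covariate model is reported, not fit
    with pytest.raises(ValueError, match="residual degrees of freedom"):
        group_compare(_table([1.0, 2.0], [1.5, 2.5]), "y")


def test_association_recovers_slope_sign():
    rng = np.random.default_rng(2)
    sev = rng.uniform(8, 30, 20)
    t = pd.DataFrame({
        "severity_score": sev,
        "y": 2.0 * sev + rng.normal(0, 1.0, 20),
        "study_id": ["a", "b"] * 10,
        "scanner_id": ["s1", "s1", "s2", "s2"] * 5,
        "age": rng.uniform(20, 40, 20),
    })
    res = association_test(t, "y", "severity_score")
    assert res.slope > 0 and res.p_value < 1e-6


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def _toy_maps(n, shape, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    maps = rng.normal(0, 1, (n,) + shape)
    x = np.array([1.0, 0.0] * (n // 2))
    maps[x > 0.5, :2, :2, :1] += effect
    cov = np.column_stack([rng.uniform(20, 40, n)])
    return maps, x, cov


def test_corrected_p_lower_bound_and_determinism():
    grid = Grid((4, 4, 2), 1.0, (0.0, 0.0, 0.0))
    mask = np.ones(grid.shape, bool)
    maps, x, cov = _toy_maps(12, grid.shape, effect=3.0, seed=7)
    res = permutation_test(maps, mask, x, cov, grid, n_perm=50, rng_seed=3)
    p = res.corrected_p[mask]
    assert (p >= 1.0 / res.n_perm - 1e-12).all() and (p <= 1.0).all()
    assert res.warnings  # n_perm below 100 is flagged in the run log
    res2 = permutation_test(maps, mask, x, cov, grid, n_perm=50, rng_seed=3)
    assert np.array_equal(res.corrected_p, res2.corrected_p)


def test_permutation_input_validation():
    grid = Grid((3, 3, 3), 1.0, (0.0, 0.0, 0.0))
    mask = np.ones(grid.shape, bool)
    maps, x, cov = _toy_maps(6, grid.shape)
    with pytest.raises(ValueError, match="at least 8"):
        permutation_test(maps, mask, x, cov, grid, n_perm=10)
    maps12, x12, cov12 = _toy_maps(12, grid.shape)
    with pytest.raises(ValueError, match="constant"):
        permutation_test(maps12, mask, np.ones(12), cov12, grid, n_perm=10)


def test_cluster_descriptors():
    grid = Grid((6, 6, 6), 1.0, (10.0, -5.0, 0.0))
    mask = np.ones(grid.shape, bool)
    p = np.ones(grid.shape)
    assert len(cluster_descriptors(p, mask, grid)) == 0
    p[2, 3, 4] = 0.01
    single = cluster_descriptors(p, mask, grid)
    assert len(single) == 1
    assert single.iloc[0][["cog_x_mm", "cog_y_mm", "cog_z_mm"]].tolist() == [12.0, -2.0, 4.0]
    assert single.iloc[0]["volume_mm3"] == 1.0
    p[4:6, 4:6, 4:6] = 0.01  # second, larger cluster
    two = cluster_descriptors(p, mask, grid)
    assert len(two) == 2
    assert two.iloc[0]["volume_mm3"] > two.iloc[1]["volume_mm3"]
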