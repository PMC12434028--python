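import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striocomp import classify_voxels, compute_bias_probabilities, \
    build_high_bias_masks, compartment_volumes, largest_cluster_volume, \
    centroid_relative_locations, radial_diffusivity
from striocomp.grid import Grid
from striocomp.parcellation import (INDETERMINATE, MATRIX_LIKE, STRIOSOME_LIKE,
                                    UNSEEDED, ProbabilityMaps)
from striocomp.tracking import StreamlineCounts


def _counts(grid, voxels, matrix, striosome, launched=1000):
    sv = np.array(voxels)
    c = np.column_stack([matrix, striosome]).astype(np.int64)
    return StreamlineCounts(sv, ("matrix", "striosome"), c, launched,
                            grid.voxel_volume)


@pytest.fixture
def small_grid():
    return Grid((4, 4, 4), 1.0, (0.0, 0.0, 0.0))


def test_bias_probabilities_arithmetic(small_grid):
    voxels = [(0, 0, 0), (1, 0, 0), (2, 0, 0)]
    mask = np.zeros(small_grid.shape, bool)
    for v in voxels:
        mask[v] = True
    counts = _counts(small_grid, voxels, [990, 0, 55], [10, 0, 45])
    prob = compute_bias_probabilities(counts, mask, small_grid, min_total_count=10)
    assert prob.p_matrix[0, 0, 0] == pytest.approx(0.99)
    assert not prob.seeded_mask[1, 0, 0]          # (0, 0) -> unseeded
    assert prob.p_matrix[2, 0, 0] == pytest.approx(0.55)
    assert prob.p_striosome[2, 0, 0] == pytest.approx(0.45)
    prob.validate()  # sums to one on seeded voxels
    with pytest.raises(ValueError, match="negative"):
        compute_bias_probabilities(
            _counts(small_grid, voxels, [-1, 0, 0], [1, 0, 0]), mask, small_grid)


def _prob_from_pm(grid, mask, pm_values, seeded=None):
    pm = np.zeros(grid.shape)
    pm[mask] = pm_values
    seeded_mask = mask.copy() if seeded is None else seeded
    ps = np.where(seeded_mask, 1.0 - pm, 0.0)
    pm = np.where(seeded_mask, pm, 0.0)
    return ProbabilityMaps(grid, pm, ps, seeded_mask, mask, 10)


def test_classification_boundaries(small_grid):
    mask = np.zeros(small_grid.shape, bool)
    mask[:3, 0, 0] = True
    prob = _prob_from_pm(small_grid, mask, [0.55, 0.50, 0.30])
    parc = classify_voxels(prob)
    assert parc.labels[0, 0, 0] == MATRIX_LIKE       # P >= 0.55 inclusive
    assert parc.labels[1, 0, 0] == INDETERMINATE
    assert parc.labels[2, 0, 0] == STRIOSOME_LIKE    # complement >= 0.55
    with pytest.raises(ValueError, match="bias_threshold"):
        classify_voxels(prob, bias_threshold=0.5)
    with pytest.raises(ValueError, match="band"):
        classify_voxels(prob, bias_threshold=0.55, indeterminate_band=(0.4, 0.6))


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=5, max_size=30),
       st.lists(st.booleans(), min_size=5, max_size=30))
def test_partition_and_complement_symmetry(pvals, seeded_flags):
    n = min(len(pvals), len(seeded_flags))
    grid = Grid((n, 1, 1), 1.0, (0.0, 0.0, 0.0))
    mask = np.ones(grid.shape, bool)
    seeded = np.array(seeded_flags[:n]).reshape(grid.shape)
    prob = _prob_from_pm(grid, mask, pvals[:n], seeded)
    parc = classify_voxels(prob)
    counts = parc.counts()
    assert sum(counts.values()) == int(mask.sum())  # exact partition
    swapped = ProbabilityMaps(grid, prob.p_striosome, prob.p_matrix,
                              prob.seeded_mask, mask, 10)
    parc_sw = classify_voxels(swapped)
    assert np.array_equal(parc.labels == MATRIX_LIKE, parc_sw.labels == STRIOSOME_LIKE)
    assert np.array_equal(parc.labels == STRIOSOME_LIKE, parc_sw.labels == MATRIX_LIKE)
    assert np.array_equal(parc.labels == INDETERMINATE, parc_sw.labels == INDETERMINATE)


def test_compartment_volumes_definition(small_grid):
    mask = np.zeros(small_grid.shape, bool)
    mask[:2, :2, :2] = True  # 8-voxel "nucleus"
    nuclei = mask.astype(np.int8)
    prob = _prob_from_pm(small_grid, mask, [0.9] * 8)
    parc = classify_voxels(prob)
    vols = compartment_volumes(parc, nuclei, etiv=1e6, nucleus_labels={"putamen": 1})
    row = vols[(vols.nucleus == "putamen") & (vols.measure == "matrix_like")].iloc[0]
    assert row.raw_mm3 == pytest.approx(8.0)
    assert row.normalized == pytest.approx(8e-6)
    row = vols[(vols.nucleus == "putamen") & (vols.measure == "striosome_like")].iloc[0]
    assert row.raw_mm3 == 0.0
    with pytest.raises(ValueError, match="eTIV"):
        compartment_volumes(parc, nuclei, etiv=0.0, nucleus_labels={"putamen": 1})


def test_high_bias_masks_sizes_and_truncation():
    grid = Grid((10, 10, 10), 1.0, (0.0, 0.0, 0.0))
    mask = np.ones(grid.shape, bool)  # 1000-voxel striatum
    rng = np.random.default_rng(0)
    pm = np.where(rng.random(grid.shape) < 0.5, rng.uniform(0.6, 1.0, grid.shape),
                  rng.uniform(0.0, 0.4, grid.shape))
    prob = ProbabilityMaps(grid, pm, 1.0 - pm, mask, mask, 10)
    hb = build_high_bias_masks(prob, mask, target_fraction=0.13)
    assert hb.matrix_mask.sum() == hb.striosome_mask.sum() == 130
    assert not (hb.matrix_mask & hb.striosome_mask).any()
    # striosome-poor fixture: only 90 eligible -> both truncated to 90
    pm_poor = pm.copy()
    strio_eligible = np.flatnonzero((1.0 - pm_poor).ravel() > 0.5)
    drop = strio_eligible[90:]
    pm_flat = pm_poor.ravel()
    pm_flat[drop] = 0.5  # no longer striosome-eligible
    prob_poor = ProbabilityMaps(grid, pm_poor, 1.0 - pm_poor, mask, mask, 10)
    hb_poor = build_high_bias_masks(prob_poor, mask, target_fraction=0.13)
    assert hb_poor.matrix_mask.sum() == hb_poor.striosome_mask.sum() == 90
    with pytest.raises(ValueError, match="target_fraction"):
        build_high_bias_masks(prob, mask, target_fraction=0.6)


def test_high_bias_tie_breaking_is_deterministic():
    grid = Grid((4, 4, 4), 1.0, (0.0, 0.0, 0.0))
    mask = np.ones(grid.shape, bool)
    pm = np.full(grid.shape, 0.8)  # ties within each compartment
    pm.ravel()[32:] = 0.2
    prob = ProbabilityMaps(grid, pm, 1.0 - pm, mask, mask, 10)
    a = build_high_bias_masks(prob, mask, target_fraction=0.2)
    b = build_high_bias_masks(prob, mask, target_fraction=0.2)
    assert np.array_equal(a.matrix_mask, b.matrix_mask)
    # ties resolved by ascending flat index
    expected = np.zeros(64, bool)
    expected[:13] = True
    assert np.array_equal(a.matrix_mask.ravel(), expected)
    expected_s = np.zeros(64, bool)
    expected_s[32:45] = True
    assert np.array_equal(a.striosome_mask.ravel(), expected_s)


def test_largest_cluster_connectivity():
    mask = np.zeros((4, 4, 4), bool)
    mask[0, 0, 0] = mask[1, 1, 1] = True  # corner-touching pair
    assert largest_cluster_volume(mask, 1.0, connectivity=26) == 2.0
    assert largest_cluster_volume(mask, 1.0, connectivity=6) == 1.0
    single = np.zeros((3, 3, 3), bool)
    single[1, 1, 1] = True
    assert largest_cluster_volume(single, 1.5 ** 3) == pytest.approx(3.375)
    assert largest_cluster_volume(np.zeros((3, 3, 3), bool), 1.0) == 0.0


def test_centroid_relative_locations():
    grid = Grid((5, 5, 5), 1.0, (0.0, 0.0, 0.0))
    nucleus = np.ones(grid.shape, bool)
    assert np.allclose(centroid_relative_locations(nucleus, nucleus, grid), 0.0)
    pair = np.zeros(grid.shape, bool)
    pair[2, 0, 2] = pair[2, 4, 2] = True  # symmetric about the centroid in y
    off = centroid_relative_locations(pair, nucleus, grid)
    assert off[1] == pytest.approx(0.0)
    with pytest.raises(ValueError, match="empty"):
        centroid_relative_locations(np.zeros(grid.shape, bool), nucleus, grid)
    outside = np.zeros(grid.shape, bool)
    outside[0, 0, 0] = True
    with pytest.raises(ValueError, match="inside"):
        centroid_relative_locations(outside, ~outside, grid)


def test_radial_diffusivity():
    rd = np.zeros((2, 1, 1, 3))
    rd[0, 0, 0] = (7e-4, 7e-4, 7e-4)
    rd[1, 0, 0] = (1.5e-3, 5e-4, 3e-4)
    m0 = np.array([[[True]], [[False]]])
    assert radial_diffusivity(rd, m0) == pytest.approx(7e-4)
    assert radial_diffusivity(rd, ~m0) == pytest.approx(4e-4)
    rd[0, 0, 0] = (1e-3, 0.0, 0.0)
    assert radial_diffusivity(rd, m0) == 0.0
    rd[0, 0, 0] = (1e-4, 5e-4, 3e-4)  # unordered
    with pytest.raises(ValueError, match="l1 >= l2"):
        radial_diffusivity(rd, m0)


def test_threshold_sweep_monotonic(default_parcellation):
    prob = default_parcellation.prob
    fractions = []
    for thr in (0.55, 0.7, 0.87):
        parc = classify_voxels(prob, bias_threshold=thr)
        fractions.append((parc.labels == STRIOSOME_LIKE).sum())
    assert fractions[0] >= fractions[1] >= fractions[2]
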