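import numpy as np
import pytest

from conftest import make_field
from oracles import ruin_absorption_right

from striocomp import TrackingParams, track_classification, track_streamline_mode


def _corridor_field(n=14):
    """A straight +x corridor on a (n, 3, 3) grid."""
    fills = [((i, j, k), [((1, 0, 0), 1.0)])
             for i in range(n) for j in range(3) for k in range(3)]
    return make_field((n, 3, 3), fills)


def _mask(shape, where):
    m = np.zeros(shape, dtype=bool)
    for v in where:
        m[v] = True
    return m


def test_forced_geometry_all_streamlines_reach_target():
    field = _corridor_field()
    shape = field.grid.shape
    seed = _mask(shape, [(1, 1, 1)])
    target_a = _mask(shape, [(8, j, k) for j in range(3) for k in range(3)])
    target_b = _mask(shape, [(12, j, k) for j in range(3) for k in range(3)])
    counts = track_classification(field, seed, {"A": target_a, "B": target_b}, None,
                                  TrackingParams(samples_per_seed_voxel=5000, rng_seed=0))
    assert counts.counts[0].tolist() == [5000, 0]


def test_curvature_violation_discards_all_streamlines():
    # alternating voxel columns whose directions have pairwise dot 0.1,
    # below the 0.2 curvature threshold (and -0.1 after the antipodal flip)
    d1 = (1.0, 0.0, 0.0)
    d2 = (0.1, np.sqrt(1 - 0.01), 0.0)
    n = 14
    fills = []
    for i in range(n):
        for j in range(8):
            for k in range(3):
                fills.append(((i, j, k), [(d1 if i % 2 == 0 else d2, 1.0)]))
    field = make_field((n, 8, 3), fills)
    shape = field.grid.shape
    seed = _mask(shape, [(0, 1, 1)])
    target = _mask(shape, [(9, j, k) for j in range(8) for k in range(3)])
    counts = track_classification(field, seed, {"A": target}, None,
                                  TrackingParams(samples_per_seed_voxel=500, rng_seed=0))
    assert counts.counts.sum() == 0


def test_targets_beyond_step_budget_are_unreachable():
    field = _corridor_field()
    shape = field.grid.shape
    seed = _mask(shape, [(1, 1, 1)])
    target = _mask(shape, [(10, 1, 1)])  # 9 mm away
    params = TrackingParams(samples_per_seed_voxel=200, max_steps=5,
                            step_length_mm=0.5, rng_seed=0)  # reach: 2.5 mm
    counts = track_classification(field, seed, {"A": target}, None, params)
    assert counts.counts.sum() == 0


def test_reproducibility_and_conservation(default_phantom):
    s = default_phantom
    grid = s.grid
    seeds = np.isin(s.nuclei, (2, 4))
    targets = {"matrix": s.bait_atlas.composite("matrix", grid.hemisphere_mask("right")),
               "striosome": s.bait_atlas.composite("striosome", grid.hemisphere_mask("right"))}
    params = TrackingParams(samples_per_seed_voxel=30, rng_seed=5)
    a = track_classification(s.orientation, seeds, targets,
                             grid.hemisphere_mask("left"), params)
    b = track_classification(s.orientation, seeds, targets,
                             grid.hemisphere_mask("left"), params)
    assert np.array_equal(a.counts, b.counts)
    assert (a.counts.sum(axis=1) <= params.samples_per_seed_voxel).all()
    assert (a.counts >= 0).all()
    c = track_classification(s.orientation, seeds, targets, grid.hemisphere_mask("left"),
                             TrackingParams(samples_per_seed_voxel=30, rng_seed=6))
    assert not np.array_equal(a.counts, c.counts)


def test_enlarging_a_target_never_decreases_its_count():
    field = _corridor_field()
    shape = field.grid.shape
    seed = _mask(shape, [(1, 1, 1)])
    small = _mask(shape, [(8, 1, 1)])
    big = small | _mask(shape, [(8, j, k) for j in range(3) for k in range(3)])
    params = TrackingParams(samples_per_seed_voxel=500, rng_seed=3)
    n_small = track_classification(field, seed, {"A": small}, None, params).counts.sum()
    n_big = track_classification(field, seed, {"A": big}, None, params).counts.sum()
    assert n_big >= n_small


def test_absorption_matches_markov_chain_closed_form():
    """On a 1D chain with a 0.7/0.3 direction mixture the tracker's target
    frequencies follow gambler's-ruin absorption probabilities."""
    n, p_step = 12, 0.7
    fills = [((i, j, k), [((1, 0, 0), p_step), ((-1, 0, 0), 1 - p_step)])
             for i in range(n) for j in range(3) for k in range(3)]
    field = make_field((n, 3, 3), fills)
    shape = field.grid.shape
    left = _mask(shape, [(0, j, k) for j in range(3) for k in range(3)])
    right = _mask(shape, [(n - 1, j, k) for j in range(3) for k in range(3)])
    start_col = 4
    seed = _mask(shape, [(start_col, 1, 1)])
    samples = 4000
    params = TrackingParams(curvature_threshold=-1.0, antipodal=False,
                            step_length_mm=1.0, samples_per_seed_voxel=samples,
                            max_steps=4000, rng_seed=9)
    counts = track_classification(field, seed, {"left": left, "right": right},
                                  None, params)
    p_right_hat = counts.counts[0, 1] / samples
    expected = ruin_absorption_right(p_step, start_col, n - 1)
    se = np.sqrt(expected * (1 - expected) / samples)
    assert counts.counts[0].sum() == samples  # every walk is absorbed
    assert abs(p_right_hat - expected) <= 3 * se


def test_streamline_mode_normalization_and_avoid():
    field = _corridor_field()
    shape = field.grid.shape
    target = _mask(shape, [(10, j, k) for j in range(3) for k in range(3)])
    one_col = _mask(shape, [(1, j, k) for j in range(3) for k in range(3)])
    two_col = one_col | _mask(shape, [(2, j, k) for j in range(3) for k in range(3)])
    params = TrackingParams(samples_per_seed_voxel=2000, rng_seed=4)
    n1 = track_streamline_mode(field, one_col, target, None, None, params)
    n2 = track_streamline_mode(field, two_col, target, None, None, params)
    assert n1 > 0
    assert abs(n1 - n2) / n1 < 0.1  # normalized counts match within sampling error
    # an avoid mask across the only corridor blocks everything
    wall = _mask(shape, [(6, j, k) for j in range(3) for k in range(3)])
    assert track_streamline_mode(field, one_col, target, None, wall, params) == 0.0


def test_matched_compartments_route_more_streamlines(default_phantom):
    s = default_phantom
    grid = s.grid
    hemi = grid.hemisphere_mask("right")
    mat_comp = s.bait_atlas.composite("matrix", hemi)
    str_comp = s.bait_atlas.composite("striosome", hemi)
    strio_vox = (s.gt_compartment == 2) & np.isin(s.nuclei, (2, 4))
    mat_vox = (s.gt_compartment == 1) & np.isin(s.nuclei, (2, 4))
    params = TrackingParams(samples_per_seed_voxel=60, rng_seed=2)
    matched_s = track_streamline_mode(s.orientation, strio_vox, str_comp, None,
                                      mat_comp, params)
    mismatched_s = track_streamline_mode(s.orientation, strio_vox, mat_comp, None,
                                         str_comp, params)
    matched_m = track_streamline_mode(s.orientation, mat_vox, mat_comp, None,
                                      str_comp, params)
    mismatched_m = track_streamline_mode(s.orientation, mat_vox, str_comp, None,
                                         mat_comp, params)
    assert matched_s > mismatched_s
    assert matched_m > mismatched_m


def test_input_validation():
    field = _corridor_field()
    shape = field.grid.shape
    seed = _mask(shape, [(1, 1, 1)])
    target = _mask(shape, [(8, 1, 1)])
    params = TrackingParams(samples_per_seed_voxel=10)
    with pytest.raises(ValueError, match="seed mask is empty"):
        track_classification(field, np.zeros(shape, bool), {"A": target}, None, params)
    with pytest.raises(ValueError, match="disjoint from the seed"):
        track_classification(field, target, {"A": target}, None, params)
    with pytest.raises(ValueError, match="exclusion"):
        track_classification(field, seed, {"A": target}, target, params)
    with pytest.raises(ValueError, match="disjoint"):
        track_streamline_mode(field, seed, target, None, target, params)
    with pytest.raises(ValueError):
        TrackingParams(curvature_threshold=1.5).validate()
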