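import numpy as np
import pytest

from striocomp import TrackingParams, build_phantom, parcellate_subject
from striocomp.grid import Grid, OrientationField


@pytest.fixture(scope="session")
def default_phantom():
    """The default high-contrast phantom used across tests."""
    return build_phantom(rng_seed=1)


@pytest.fixture(scope="session")
def default_parcellation(default_phantom):
    """One full single-subject parcellation (reduced sampling for speed)."""
    params = TrackingParams(samples_per_seed_voxel=300, rng_seed=7)
    return parcellate_subject(default_phantom, params)


def make_field(shape, fills, voxel_size=1.0, origin=(0.0, 0.0, 0.0), k=2):
    """Small hand-built orientation field.

    ``fills`` is a list of (mask_or_index, [(direction, weight), ...]).
    """
    grid = Grid(tuple(shape), voxel_size, tuple(origin))
    dirs = np.zeros(tuple(shape) + (k, 3), dtype=np.float32)
    weights = np.zeros(tuple(shape) + (k,), dtype=np.float32)
    for where, entries in fills:
        for slot, (d, w) in enumerate(entries):
            d = np.asarray(d, dtype=np.float32)
            d = d / np.linalg.norm(d)
            dirs[where + (slot,)] = d
            weights[where + (slot,)] = w
    return OrientationField(grid, dirs, weights)
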