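"""Voxel grids, affines and fiber-orientation fields.

All volumes in this package live on a single right-anterior-superior (RAS)
voxel grid with an isotropic voxel size and a diagonal affine.  World
coordinates are millimetres; "rostral" is +y and "ventral" is -z.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D binary structure for 6-, 18- or 26-connected component labelling."""
    if connectivity not in (6, 18, 26):
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


@dataclass(frozen=True)
class Grid:
    """An isotropic RAS voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along x (right), y (anterior), z (superior).
    voxel_size
        Edge length of a voxel in mm.
    origin
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_size) ** 3

    def world(self, ijk: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel indices (…, 3)."""
        return np.asarray(ijk, dtype=float) * self.voxel_size + np.asarray(self.origin)

    def coords(self) -> np.ndarray:
        """World coordinates of every voxel, shape ``shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.world(idx)

    def hemisphere_mask(self, side: str) -> np.ndarray:
        """Boolean mask of the left (world x < 0) or right (x >= 0) half."""
        x = np.arange(self.shape[0]) * self.voxel_size + self.origin[0]
        half = x >= 0 if side == "right" else x < 0
        return np.broadcast_to(half[:, None, None], self.shape).copy()


@dataclass
class OrientationField:
    """Per-voxel mixture of fiber directions.

    ``dirs`` has shape ``grid.shape + (K, 3)`` (unit vectors, world axes) and
    ``weights`` shape ``grid.shape + (K,)``; weights are >= 0 and sum to one
    wherever the field is defined, and to zero outside.
    """

    grid: Grid
    dirs: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.dirs.shape[:3] != tuple(self.grid.shape):
            raise ValueError("orientation dirs do not match the grid shape")
        if self.weights.shape != self.dirs.shape[:4]:
            raise ValueError("orientation weights do not match dirs")

    @property
    def defined_mask(self) -> np.ndarray:
        return self.weights.sum(axis=-1) > 0


def labeled_components(mask: np.ndarray, connectivity: int = 26):
    """Connected components of a binary mask; returns (labels, n)."""
    return ndimage.label(mask, structure=connectivity_structure(connectivity))


def largest_component_size(mask: np.ndarray, connectivity: int = 26) -> int:
    """Voxel count of the largest connected component (0 for an empty mask)."""
    labels, n = labeled_components(mask, connectivity)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())
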