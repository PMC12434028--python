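"""Connectivity-based striatal compartment parcellation.

Streamline counts to the matrix-favoring and striosome-favoring bait
composites are turned into voxelwise connection probabilities (which sum to
one on every seeded voxel), voxels are classified as matrix-like
(P >= 0.55), striosome-like, indeterminate (P in [0.45, 0.55)) or unseeded,
and the derived measures of the analysis are computed: compartment volumes
(raw and eTIV-normalized), equal-volume high-bias masks, largest-cluster
volumes, centroid-relative locations, and radial diffusivity.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import Grid, connectivity_structure, labeled_components
from .tracking import StreamlineCounts

# parcellation labels (0 = outside the striatal mask)
MATRIX_LIKE, STRIOSOME_LIKE, INDETERMINATE, UNSEEDED = 1, 2, 3, 4
LABEL_NAMES = {
    MATRIX_LIKE: "matrix_like",
    STRIOSOME_LIKE: "striosome_like",
    INDETERMINATE: "indeterminate",
    UNSEEDED: "unseeded",
}


@dataclass
class ProbabilityMaps:
    """Voxelwise compartment connection probabilities over the striatum."""

    grid: Grid
    p_matrix: np.ndarray
    p_striosome: np.ndarray
    seeded_mask: np.ndarray
    striatal_mask: np.ndarray
    min_total_count: int

    def validate(self) -> None:
        s = self.seeded_mask
        total = self.p_matrix[s] + self.p_striosome[s]
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("p_matrix + p_striosome must equal 1 on seeded voxels")


@dataclass
class CompartmentParcellation:
    """Categorical compartment-like labels over the striatal mask."""

    grid: Grid
    labels: np.ndarray
    striatal_mask: np.ndarray
    bias_threshold: float = 0.55
    indeterminate_band: tuple[float, float] = (0.45, 0.55)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def counts(self) -> dict[str, int]:
        return {name: int((self.labels == lab).sum()) for lab, name in LABEL_NAMES.items()}


@dataclass
class HighBiasMasks:
    """Equal-volume masks of the most compartment-biased voxels."""

    matrix_mask: np.ndarray
    striosome_mask: np.ndarray
    target_fraction: float = 0.13

    def validate(self) -> None:
        if self.matrix_mask.sum() != self.striosome_mask.sum():
            raise ValueError("high-bias masks must have equal volume")
        if (self.matrix_mask & self.striosome_mask).any():
            raise ValueError("high-bias masks must be disjoint")


def compute_bias_probabilities(
    counts: StreamlineCounts | Sequence[StreamlineCounts],
    striatal_mask: np.ndarray,
    grid: Grid,
    min_total_count: int = 10,
    matrix_target: str = "matrix",
    striosome_target: str = "striosome",
) -> ProbabilityMaps:
    """Voxelwise probability of connecting to each compartment's baits.

    For every seed voxel with at least ``min_total_count`` target-reaching
    streamlines, ``p_matrix = matrix count / (matrix + striosome counts)``
    (and complementarily for the striosome); voxels below the floor are
    left unseeded.  Accepts one :class:`StreamlineCounts` or a sequence
    (e.g. one per hemisphere).
    """
    if isinstance(counts, StreamlineCounts):
        counts = [counts]
    p_matrix = np.zeros(grid.shape)
    p_striosome = np.zeros(grid.shape)
    seeded = np.zeros(grid.shape, dtype=bool)
    covered = np.zeros(grid.shape, dtype=bool)
    for c in counts:
        if (c.counts < 0).any():
            raise ValueError("negative streamline counts")
        mi = c.target_names.index(matrix_target)
        si = c.target_names.index(striosome_target)
        i, j, k = c.seed_voxels.T
        covered[i, j, k] = True
        m = c.counts[:, mi].astype(float)
        s = c.counts[:, si].astype(float)
        total = m + s
        ok = total >= min_total_count
        with np.errstate(invalid="ignore", divide="ignore"):
            pm = np.where(ok, m / np.where(total > 0, total, 1.0), 0.0)
        p_matrix[i, j, k] = pm
        p_striosome[i, j, k] = np.where(ok, 1.0 - pm, 0.0)
        seeded[i, j, k] = ok
    if not covered[striatal_mask].all():
        raise ValueError("streamline counts do not cover the striatal mask")
    return ProbabilityMaps(grid, p_matrix, p_striosome, seeded, striatal_mask,
                           int(min_total_count))


def classify_voxels(prob: ProbabilityMaps, bias_threshold: float = 0.55,
                    indeterminate_band: tuple[float, float] | None = None) -> CompartmentParcellation:
    """Label voxels matrix-like / striosome-like / indeterminate / unseeded.

    A voxel is matrix-like iff ``p_matrix >= bias_threshold`` (inclusive),
    striosome-like iff ``p_striosome >= bias_threshold``, indeterminate
    otherwise; unseeded voxels pass through.
    """
    if not (0.5 < bias_threshold <= 1.0):
        raise ValueError("bias_threshold must lie in (0.5, 1]")
    if indeterminate_band is None:
        indeterminate_band = (round(1.0 - bias_threshold, 12), bias_threshold)
    lo, hi = indeterminate_band
    if not np.isclose(lo, 1.0 - hi) or not np.isclose(hi, bias_threshold):
        raise ValueError("indeterminate band must be the complement band "
                         "[1 - threshold, threshold)")
    prob.validate()
    labels = np.zeros(prob.grid.shape, dtype=np.int8)
    striatal = prob.striatal_mask
    seeded = prob.seeded_mask & striatal
    labels[striatal] = UNSEEDED
    labels[seeded & (prob.p_matrix >= bias_threshold)] = MATRIX_LIKE
    labels[seeded & (prob.p_striosome >= bias_threshold)] = STRIOSOME_LIKE
    ind = seeded & (prob.p_matrix < bias_threshold) & (prob.p_striosome < bias_threshold)
    labels[ind] = INDETERMINATE
    return CompartmentParcellation(prob.grid, labels, striatal, bias_threshold,
                                   (float(lo), float(hi)))


def compartment_volumes(parc: CompartmentParcellation, nuclei: np.ndarray,
                        etiv: float, nucleus_labels: dict[str, int]) -> pd.DataFrame:
    """Raw (mm^3) and eTIV-normalized compartment-like volumes per nucleus.

    Rows cover each named nucleus mask and each parcellation label plus the
    whole-nucleus volume; normalized volume is the plain ratio raw / eTIV.
    """
    if etiv <= 0:
        raise ValueError("eTIV must be positive")
    if parc.labels.shape != nuclei.shape:
        raise ValueError("parcellation and nuclei grids differ")
    vv = parc.grid.voxel_volume
    rows = []
    for name, lab in nucleus_labels.items():
        nmask = nuclei == lab if np.isscalar(lab) else np.isin(nuclei, lab)
        raw = float(nmask.sum()) * vv
        rows.append({"nucleus": name, "measure": "nucleus", "raw_mm3": raw,
                     "normalized": raw / etiv})
        for plab, pname in LABEL_NAMES.items():
            r = float((nmask & (parc.labels == plab)).sum()) * vv
            rows.append({"nucleus": name, "measure": pname, "raw_mm3": r,
                         "normalized": r / etiv})
    return pd.DataFrame(rows)


def build_high_bias_masks(prob: ProbabilityMaps, striatal_mask: np.ndarray | None = None,
                          target_fraction: float = 0.13) -> HighBiasMasks:
    """Equal-volume masks of each compartment's most-biased voxels.

    Selects, per compartment, up to ``target_fraction`` of the striatal
    volume from voxels whose bias exceeds 0.5, in decreasing bias order
    (ties broken by flat voxel index); the larger selection is truncated by
    dropping its lowest-bias members so the two masks always match in size.
    """
    if not (0.0 < target_fraction <= 0.5):
        raise ValueError("target_fraction must lie in (0, 0.5]")
    striatal = prob.striatal_mask if striatal_mask is None else striatal_mask
    n_target = int(round(target_fraction * int(striatal.sum())))
    masks = {}
    sel_idx = {}
    for key, p in (("matrix", prob.p_matrix), ("striosome", prob.p_striosome)):
        eligible = striatal & prob.seeded_mask & (p > 0.5)
        flat = np.flatnonzero(eligible.ravel())
        bias = p.ravel()[flat]
        order = np.lexsort((flat, -bias))  # bias desc, then flat index asc
        sel_idx[key] = flat[order]
    n_each = min(n_target, len(sel_idx["matrix"]), len(sel_idx["striosome"]))
    for key in ("matrix", "striosome"):
        m = np.zeros(prob.grid.shape, dtype=bool)
        m.ravel()[sel_idx[key][:n_each]] = True
        masks[key] = m
    out = HighBiasMasks(masks["matrix"], masks["striosome"], float(target_fraction))
    out.validate()
    return out


def largest_cluster_volume(mask: np.ndarray, voxel_volume: float,
                           connectivity: int = 26) -> float:
    """Volume (mm^3) of the largest connected component of a binary mask."""
    labels, n = labeled_components(mask.astype(bool), connectivity)
    if n == 0:
        return 0.0
    return float(np.bincount(labels.ravel())[1:].max()) * voxel_volume


def centroid_relative_locations(mask: np.ndarray, nucleus_mask: np.ndarray,
                                grid: Grid) -> np.ndarray:
    """Mean world offset (mm) of mask voxels from their nucleus centroid.

    Axes follow the RAS convention: +y is rostral, -z is ventral.
    """
    if not mask.any():
        raise ValueError("empty mask")
    if (mask & ~nucleus_mask).any():
        raise ValueError("mask must lie inside the nucleus mask")
    centroid = grid.world(np.argwhere(nucleus_mask)).mean(axis=0)
    return grid.world(np.argwhere(mask)).mean(axis=0) - centroid


def radial_diffusivity(rd_field: np.ndarray, mask: np.ndarray) -> float:
    """Mean radial diffusivity over a mask: mean of (lambda2 + lambda3) / 2."""
    lam = rd_field[mask]
    if lam.size == 0:
        raise ValueError("empty mask")
    if (np.diff(lam, axis=1) > 1e-12).any() or (lam < 0).any():
        raise ValueError("eigenvalue triples must satisfy l1 >= l2 >= l3 >= 0")
    return float(((lam[:, 1] + lam[:, 2]) / 2.0).mean())
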