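"""Leave-one-bait-out (N-1) somatotopic zone mapping.

Re-parcellating the striatum with nine of the ten bait regions and
subtracting the result from the full parcellation quantifies the left-out
region's voxelwise influence on compartment bias.  Each striatal voxel is
assigned to the region of maximal absolute influence (which makes zones
disjoint by construction); zones are then truncated to their top-influence
voxels so their sizes stay comparable.  Compartment balance inside a zone is
summarized by the normalized volume ratio
(V_dominant - V_nondominant) / (V_dominant + V_nondominant).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parcellation import (MATRIX_LIKE, STRIOSOME_LIKE, CompartmentParcellation,
                           ProbabilityMaps)


@dataclass
class InfluenceMap:
    """Signed voxelwise influence of one bait region on matrix-map bias.

    ``values = full p_matrix - N-1 p_matrix`` (matrix-map convention: the
    two compartment maps are complementary, so one signed map suffices);
    zero wherever either parcellation left the voxel unseeded.
    """

    region: str
    values: np.ndarray
    seeded_mask: np.ndarray


@dataclass
class SomatotopicZoneSet:
    """Ten disjoint striatal zones, one per bait region."""

    zones: dict[str, np.ndarray]
    floor: dict[str, float]
    size_bound: float

    def validate(self) -> None:
        names = list(self.zones)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if (self.zones[a] & self.zones[b]).any():
                    raise ValueError(f"zones {a!r} and {b!r} overlap")
        sizes = [int(z.sum()) for z in self.zones.values()]
        if min(sizes) > 0 and max(sizes) / min(sizes) > self.size_bound + 1e-9:
            raise ValueError("zone size ratio exceeds the configured bound")

    def counts(self) -> dict[str, int]:
        return {n: int(z.sum()) for n, z in self.zones.items()}


@dataclass
class ZoneRatio:
    """Normalized compartment-volume ratio of one somatotopic zone."""

    zone: str
    dominant: str
    v_dominant: float
    v_nondominant: float

    @property
    def value(self) -> float | None:
        total = self.v_dominant + self.v_nondominant
        if total <= 0:
            return None  # undefined, reported as missing
        return (self.v_dominant - self.v_nondominant) / total


def compute_influence_maps(full: ProbabilityMaps,
                           n1_maps: dict[str, ProbabilityMaps]) -> dict[str, InfluenceMap]:
    """Influence of each left-out region: full minus N-1 matrix bias."""
    out = {}
    for region, n1 in n1_maps.items():
        seeded = full.seeded_mask & n1.seeded_mask
        values = np.where(seeded, full.p_matrix - n1.p_matrix, 0.0)
        out[region] = InfluenceMap(region, values, seeded)
    return out


def n_minus_one_parcellation(subject, leave_out: str, tracking_params,
                             min_total_count: int = 10) -> ProbabilityMaps:
    """Re-parcellate with the named bait region left out of its composite.

    Runs the identical per-hemisphere tracking pipeline (same seed stream)
    with the region removed from the matrix- or striosome-favoring target
    composite.
    """
    from .pipeline import subject_probability_maps  # deferred: avoids a cycle

    if leave_out not in subject.bait_atlas.regions:
        raise ValueError(f"unknown bait region {leave_out!r}")
    return subject_probability_maps(subject, tracking_params,
                                    min_total_count=min_total_count,
                                    leave_out=leave_out)


def derive_zones(influence_maps: dict[str, InfluenceMap],
                 floor_percentile: float = 75.0,
                 size_bound: float = 4.0,
                 striatal_mask: np.ndarray | None = None) -> SomatotopicZoneSet:
    """Assign voxels to the region of maximal absolute influence.

    A voxel enters the assignment when at least one region's |influence|
    reaches that region's floor (the given percentile of its own nonzero
    |influence| distribution); argmax assignment guarantees disjointness
    (ties go to the earlier region in the input order).  Each zone is then
    truncated to its top-influence voxels so that the largest:smallest size
    ratio stays within ``size_bound``.
    """
    names = list(influence_maps)
    stack = np.stack([np.abs(influence_maps[n].values) for n in names])
    if striatal_mask is not None:
        stack = stack * striatal_mask
    floors = {}
    for i, n in enumerate(names):
        nz = stack[i][stack[i] > 0]
        if nz.size == 0:
            raise ValueError(f"region {n!r} has no voxels with nonzero influence")
        floors[n] = float(np.percentile(nz, floor_percentile))
    above = np.stack([stack[i] >= floors[n] for i, n in enumerate(names)])
    eligible = above.any(axis=0)
    masked = np.where(above, stack, -np.inf)
    winner = np.argmax(masked, axis=0)  # first max wins: fixed-order tie rule
    zones = {}
    for i, n in enumerate(names):
        z = eligible & (winner == i)
        if not z.any():
            raise ValueError(f"region {n!r} has no voxels above its influence floor")
        zones[n] = z
    # truncate large zones to their top-influence voxels
    sizes = {n: int(z.sum()) for n, z in zones.items()}
    cap = int(np.floor(min(sizes.values()) * size_bound))
    for i, n in enumerate(names):
        if sizes[n] > cap:
            flat = np.flatnonzero(zones[n].ravel())
            vals = stack[i].ravel()[flat]
            order = np.lexsort((flat, -vals))
            keep = flat[order][:cap]
            z = np.zeros_like(zones[n])
            z.ravel()[keep] = True
            zones[n] = z
    out = SomatotopicZoneSet(zones, floors, float(size_bound))
    out.validate()
    return out


def zone_ratio_statistic(parc: CompartmentParcellation, zone_mask: np.ndarray,
                         dominant: str) -> ZoneRatio:
    """Normalized compartment-volume ratio within one somatotopic zone."""
    if dominant not in ("matrix", "striosome"):
        raise ValueError("dominant must be 'matrix' or 'striosome'")
    if (zone_mask & ~parc.striatal_mask).any():
        raise ValueError("zone must lie inside the striatal mask")
    vv = parc.grid.voxel_volume
    v_mat = float((zone_mask & (parc.labels == MATRIX_LIKE)).sum()) * vv
    v_str = float((zone_mask & (parc.labels == STRIOSOME_LIKE)).sum()) * vv
    if dominant == "matrix":
        return ZoneRatio("", "matrix", v_mat, v_str)
    return ZoneRatio("", "striosome", v_str, v_mat)


def zone_ratio_table(parc: CompartmentParcellation, zone_set: SomatotopicZoneSet,
                     affinity: dict[str, str]) -> pd.DataFrame:
    """One row per zone: dominant compartment, volumes and the ratio."""
    rows = []
    for name, zone in zone_set.zones.items():
        zr = zone_ratio_statistic(parc, zone, affinity[name])
        rows.append({
            "zone": name, "dominant": zr.dominant,
            "v_dominant_mm3": zr.v_dominant, "v_nondominant_mm3": zr.v_nondominant,
            "ratio": np.nan if zr.value is None else zr.value,
            "n_voxels": int(zone.sum()),
        })
    return pd.DataFrame(rows)
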