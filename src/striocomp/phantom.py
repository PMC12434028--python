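"""Synthetic striatum phantoms with known compartment ground truth.

The phantom emulates the anatomy that connectivity-based striatal
parcellation relies on:

* two nuclei per hemisphere (caudate, putamen) rasterized as ellipsoids on a
  1 mm RAS grid, mirror-symmetric across the midline;
* a striosome compartment grown as thin, separated random-walk tubules
  (~15% of striatal volume, branch diameter capped at one voxel) embedded in
  a contiguous matrix, with the striosome biased rostrally and ventrally;
* ten extra-striatal "bait" regions (five matrix-favoring, five
  striosome-favoring) as shell wedges around each hemisphere's striatum:
  a dorsal polar cap for the matrix fan, a rostral/lateral equatorial band
  for the striosome fan;
* a fiber-orientation field that routes each striatal voxel predominantly
  toward bait wedges of its own compartment's affinity — concentrated on
  the wedge that dominates its somatotopic sector — with a configurable
  leakage toward the opposite affinity; matrix efferents ascend vertically,
  striosome efferents run horizontally, and corridor voxels carry both
  crossing fascicles, so the tracker's curvature gate keeps the two systems
  separate;
* per-voxel diffusion-tensor eigenvalue triples and an intracranial-volume
  analog (eTIV) for volume normalization.

Simulated cohorts add subject-level jitter and, for the MDD group, localized
connectivity-bias shifts: a rostral-putamen zone in which matrix-wired
voxels are rewired toward striosome-favoring regions (plus an overall
putamen volume scaling), and a severity-graded rostral-caudate zone rewired
in the opposite direction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid, OrientationField, labeled_components

# ---------------------------------------------------------------------------
# Labels and region tables
# ---------------------------------------------------------------------------

BACKGROUND = 0
CAUDATE_LEFT, CAUDATE_RIGHT, PUTAMEN_LEFT, PUTAMEN_RIGHT = 1, 2, 3, 4
NUCLEUS_LABELS = {
    "caudate_left": CAUDATE_LEFT,
    "caudate_right": CAUDATE_RIGHT,
    "putamen_left": PUTAMEN_LEFT,
    "putamen_right": PUTAMEN_RIGHT,
}
MATRIX, STRIOSOME = 1, 2
COMPARTMENT_NAMES = {MATRIX: "matrix", STRIOSOME: "striosome"}

MATRIX_REGIONS = (
    "ifg_pars_opercularis",
    "primary_motor",
    "supplementary_motor",
    "primary_somatosensory",
    "superior_parietal",
)
STRIOSOME_REGIONS = (
    "posterior_ofc",
    "anterior_insula",
    "basolateral_amygdala",
    "basal_operculum",
    "posterior_temporal_fusiform",
)
ALL_REGIONS = MATRIX_REGIONS + STRIOSOME_REGIONS

# Efferent routing is organized around two orthogonal fiber systems
# (right hemisphere; x flips for the left): matrix-favoring projections
# ascend vertically into a dorsal cap of bait wedges (the sensorimotor/
# associative cortex reached via the corona radiata), while striosome-
# favoring projections run horizontally toward an equatorial band of
# rostral/lateral limbic bait wedges.  Because the two systems are
# perpendicular, the 0.2 cos-curvature gate never lets a streamline
# committed to one affinity follow fibers of the other — the phantom analog
# of the crossing-fiber separation that makes compartment-specific tracking
# possible in real data.  Azimuths are measured from +y (rostral) toward
# +x (lateral) around each hemisphere's angular origin.
_MATRIX_POLAR_DEG = 10.0
# Azimuth centers are occupancy quantiles of the striatal voxel distribution
# around the angular origin, so the five somatotopic sectors of each fan hold
# similar striatal volumes.
_MATRIX_AZIMUTHS_DEG = (-9.0, 34.0, 93.0, 117.0, 142.0)
_STRIO_AZIMUTHS_DEG = (-10.0, 30.0, 84.0, 109.0, 137.0)


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


class InfeasibleGeometryError(ValueError):
    """Raised when the requested phantom geometry cannot be realized."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomParams:
    """Configuration of a single phantom subject.

    The defaults produce a desk-scale striatum of roughly 3,000 voxels at
    1 mm isotropic resolution with a 15% striosome fraction.
    """

    grid_shape: tuple[int, int, int] = (66, 46, 36)
    voxel_size_mm: float = 1.0
    origin_mm: tuple[float, float, float] = (-33.0, -20.0, -10.0)
    caudate_center: tuple[float, float, float] = (10.0, 6.0, 8.0)
    caudate_radii: tuple[float, float, float] = (3.2, 9.0, 5.2)
    putamen_center: tuple[float, float, float] = (18.0, 0.0, 0.0)
    putamen_radii: tuple[float, float, float] = (4.0, 8.5, 6.0)
    #: angular origin (right hemisphere, world mm) of the radial frame used
    #: for somatotopic sectors, bait wedges and corridor fibers
    angular_origin_mm: tuple[float, float, float] = (10.0, 2.5, 3.4)
    #: radius (mm) from the angular origin to bait aim points
    region_distance_mm: float = 18.5
    #: bait regions are shell wedges between these radii (mm)
    region_shell_inner_mm: float = 17.0
    region_shell_outer_mm: float = 20.5
    #: polar extent of the dorsal matrix cap and azimuthal half-widths (deg)
    matrix_cap_polar_deg: float = 50.0
    matrix_wedge_halfwidth_deg: float = 180.0
    strio_band_halfwidth_deg: float = 34.0
    strio_wedge_halfwidth_deg: float = 180.0
    striosome_fraction: float = 0.15
    fraction_tolerance: float = 0.02
    striosome_diameter_cap_mm: float = 1.25
    #: orientation-weight mass routed to opposite-affinity bait regions
    leakage: float = 0.15
    #: share of same-affinity mass concentrated on the sector-dominant region
    zone_dominance: float = 0.8
    #: rostral/ventral seeding bias (logit scale) for striosome tubules
    seed_bias_beta: float = 2.0
    #: strength of the rostroventral striosome density gradient in [0, 1)
    location_bias: float = 0.85
    walk_persistence: float = 0.75
    walk_axis_bias: float = 0.6
    max_tubule_length: int = 40
    min_components_per_hemisphere: int = 3
    #: required rostral (+y) and ventral (-z) striosome centroid offset, mm
    min_centroid_offset_mm: float = 0.3
    max_geometry_retries: int = 25
    etiv_mm3: float = 1.43e6
    #: base tensor eigenvalues (mm^2/s), sorted descending
    base_eigenvalues: tuple[float, float, float] = (1.0e-3, 6.0e-4, 4.0e-4)

    def validate(self) -> None:
        if min(self.grid_shape) < 20:
            raise ValueError("grid dimensions must be >= 20 voxels per axis")
        if not (0.5 < self.voxel_size_mm < 3.0):
            raise ValueError("voxel size must lie in (0.5, 3.0) mm")
        if not (0.05 < self.striosome_fraction < 0.4):
            raise ValueError("striosome target fraction must lie in (0.05, 0.4)")
        if self.voxel_size_mm > self.striosome_diameter_cap_mm:
            raise InfeasibleGeometryError(
                "striosome diameter cap "
                f"({self.striosome_diameter_cap_mm} mm) is smaller than one voxel "
                f"({self.voxel_size_mm} mm): single-voxel tubules would already "
                "violate the cap"
            )
        if not (0.0 <= self.leakage < 0.5):
            raise ValueError("leakage must lie in [0, 0.5)")

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.grid_shape), self.voxel_size_mm, tuple(self.origin_mm))


@dataclass
class Conversion:
    """A localized wiring override applied when building a subject.

    Within ``zone`` (a boolean grid mask), voxels whose ground-truth
    compartment matches ``from_compartment`` are wired as if they belonged to
    ``to_compartment``.  Ground-truth labels are untouched: the override
    models a shift in connectivity bias, not in histology.
    """

    zone: np.ndarray
    from_compartment: int
    to_compartment: int


@dataclass
class BaitAtlas:
    """Ten bait-region masks with compartment affinities and ground-truth
    somatotopic zones (the striatal territory each region dominates)."""

    regions: dict[str, np.ndarray]
    affinity: dict[str, str]
    gt_zone: dict[str, np.ndarray]
    centers: dict[str, dict[str, np.ndarray]]  # region -> side -> world mm

    def composite(self, affinity: str, hemi_mask: np.ndarray | None = None) -> np.ndarray:
        names = [n for n, a in self.affinity.items() if a == affinity]
        if not names:
            raise ValueError(f"unknown affinity {affinity!r}")
        out = np.zeros_like(next(iter(self.regions.values())))
        for n in names:
            out |= self.regions[n]
        if hemi_mask is not None:
            out &= hemi_mask
        return out


@dataclass
class PhantomSubject:
    """One synthetic subject: geometry, wiring, ground truth, covariates."""

    subject_id: str
    params: PhantomParams
    nuclei: np.ndarray
    gt_compartment: np.ndarray
    orientation: OrientationField
    bait_atlas: BaitAtlas
    rd_field: np.ndarray
    etiv: float
    group: str = "HC"
    severity_score: float | None = None
    scanner_id: str = "scanner_1"
    study_id: str = "study_a"
    age: float = 30.0

    @property
    def grid(self) -> Grid:
        return self.params.grid

    @property
    def striatal_mask(self) -> np.ndarray:
        return self.nuclei > 0

    def nucleus_mask(self, nucleus: str, side: str | None = None) -> np.ndarray:
        if side is None:
            labels = [NUCLEUS_LABELS[f"{nucleus}_left"], NUCLEUS_LABELS[f"{nucleus}_right"]]
        else:
            labels = [NUCLEUS_LABELS[f"{nucleus}_{side}"]]
        return np.isin(self.nuclei, labels)

    def striosome_fraction(self) -> float:
        striatal = self.striatal_mask
        return float((self.gt_compartment[striatal] == STRIOSOME).mean())


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _rasterize_nuclei(grid: Grid, params: PhantomParams,
                      putamen_scale: float = 1.0) -> np.ndarray:
    """Ellipsoid nuclei labels; hemispheres mirror in world x."""
    coords = grid.coords()
    labels = np.zeros(grid.shape, dtype=np.int8)
    pr = np.array(params.putamen_radii) * putamen_scale ** (1.0 / 3.0)
    specs = [
        (CAUDATE_LEFT, np.array(params.caudate_center) * [-1, 1, 1], np.array(params.caudate_radii)),
        (CAUDATE_RIGHT, np.array(params.caudate_center), np.array(params.caudate_radii)),
        (PUTAMEN_LEFT, np.array(params.putamen_center) * [-1, 1, 1], pr),
        (PUTAMEN_RIGHT, np.array(params.putamen_center), pr),
    ]
    for lab, center, radii in specs:
        inside = (((coords - center) / radii) ** 2).sum(axis=-1) <= 1.0
        labels[inside & (labels == 0)] = lab
    return labels


def hemisphere_centroid(params: PhantomParams, side: str) -> np.ndarray:
    """Angular origin of one hemisphere's radial frame (world mm).

    Sits slightly medial of the striatal volume centroid so that the whole
    striatum occupies lateral-of-midline azimuths.
    """
    c = np.array(params.angular_origin_mm, dtype=float)
    if side == "left":
        c = c * np.array([-1.0, 1.0, 1.0])
    return c


def _axis(polar_deg: float, azimuth_deg: float, sign: float) -> np.ndarray:
    pol, az = math.radians(polar_deg), math.radians(azimuth_deg)
    return np.array([math.sin(pol) * math.sin(az) * sign,
                     math.sin(pol) * math.cos(az), math.cos(pol)])


def region_centers(params: PhantomParams) -> dict[str, dict[str, np.ndarray]]:
    """World-mm aim points of all bait regions, per region name and side."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for side, sign in (("left", -1.0), ("right", 1.0)):
        origin = hemisphere_centroid(params, side)
        for name, az in zip(MATRIX_REGIONS, _MATRIX_AZIMUTHS_DEG):
            out.setdefault(name, {})[side] = (
                origin + params.region_distance_mm * _axis(_MATRIX_POLAR_DEG, az, sign)
            )
        for name, az in zip(STRIOSOME_REGIONS, _STRIO_AZIMUTHS_DEG):
            out.setdefault(name, {})[side] = (
                origin + params.region_distance_mm * _axis(90.0, az, sign)
            )
    return out


def _rasterize_regions(grid: Grid, params: PhantomParams,
                       centers: dict[str, dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Bait regions as angular shell wedges around each hemisphere centroid.

    Matrix-favoring regions tile a dorsal polar cap; striosome-favoring
    regions tile a rostral/lateral equatorial band.  A streamline committed
    to a fan cannot slip between that fan's wedges: together the wedges cover
    the fan's full angular footprint.
    """
    coords = grid.coords()
    masks = {name: np.zeros(grid.shape, dtype=bool) for name in ALL_REGIONS}
    for side, sign in (("left", -1.0), ("right", 1.0)):
        origin = hemisphere_centroid(params, side)
        rel = coords - origin
        r = np.linalg.norm(rel, axis=-1)
        shell = (r >= params.region_shell_inner_mm) & (r <= params.region_shell_outer_mm)
        shell &= (coords[..., 0] * sign) > 0.5  # stay within the hemisphere
        polar = np.degrees(np.arccos(np.clip(rel[..., 2] / np.maximum(r, 1e-9), -1, 1)))
        azim = np.degrees(np.arctan2(rel[..., 0] * sign, rel[..., 1]))
        # wedges tile each fan by azimuth Voronoi (window-limited), so they
        # are disjoint by construction
        for names, az_table, fan_sel, halfwidth in (
            (MATRIX_REGIONS, _MATRIX_AZIMUTHS_DEG,
             polar <= params.matrix_cap_polar_deg, params.matrix_wedge_halfwidth_deg),
            (STRIOSOME_REGIONS, _STRIO_AZIMUTHS_DEG,
             np.abs(polar - 90.0) <= params.strio_band_halfwidth_deg,
             params.strio_wedge_halfwidth_deg),
        ):
            daz = np.abs(np.stack([_wrap_deg(azim - az0) for az0 in az_table]))
            nearest = np.argmin(daz, axis=0)
            for k, name in enumerate(names):
                masks[name] |= shell & fan_sel & (nearest == k) & \
                    (daz[k] <= halfwidth)
    return masks


# ---------------------------------------------------------------------------
# Striosome tubule growth
# ---------------------------------------------------------------------------

_STEPS6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _grow_tubules(nucleus_mask: np.ndarray, target: int, rng: np.random.Generator,
                  params: PhantomParams) -> np.ndarray:
    """Grow separated single-voxel-wide striosome tubules inside one nucleus.

    Tubules are random walks with direction persistence.  A voxel may be
    added only if all of its already-striosome 26-neighbors are among the
    walker's own last three voxels, which keeps every tubule a non-self-
    adjacent chain (cross-sectional width of one voxel) and keeps distinct
    tubules at least two voxels apart, so they form separated components.
    """
    shape = nucleus_mask.shape
    strio = np.zeros(shape, dtype=bool)
    idx = np.argwhere(nucleus_mask)
    if len(idx) == 0:
        return strio
    # rostral/ventral seeding bias on normalized coordinates
    yz = idx[:, 1].astype(float), idx[:, 2].astype(float)
    yn = (yz[0] - yz[0].min()) / max(np.ptp(yz[0]), 1.0)
    zn = (yz[1] - yz[1].min()) / max(np.ptp(yz[1]), 1.0)
    seed_logit = params.seed_bias_beta * (yn - zn)
    seed_w = np.exp(seed_logit - seed_logit.max())
    # rostroventral acceptance gradient: caudodorsal growth is suppressed so
    # striosome density (not just seeding) is biased rostrally/ventrally
    u = ((yn - zn) + 1.0) / 2.0
    pacc_flat = (1.0 - params.location_bias) + params.location_bias * u
    pacc = np.zeros(shape)
    pacc[tuple(idx.T)] = pacc_flat

    in_nucleus = nucleus_mask
    nbr_offsets = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if (i, j, k) != (0, 0, 0)]
    )

    def neighbors_ok(v: tuple[int, int, int], recent: list[tuple[int, int, int]]) -> bool:
        for off in nbr_offsets:
            p = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if 0 <= p[0] < shape[0] and 0 <= p[1] < shape[1] and 0 <= p[2] < shape[2]:
                if strio[p] and p not in recent:
                    return False
        return True

    count = 0
    stall = 0
    max_walkers = 40 * max(target, 1)
    axis_dirs = (2, 3)  # +-y rows in _STEPS6
    for _ in range(max_walkers):
        if count >= target:
            break
        order = rng.choice(len(idx), size=min(len(idx), 200), replace=False,
                           p=seed_w / seed_w.sum())
        seed_v = None
        for i in order:
            v = tuple(int(a) for a in idx[i])
            if not strio[v] and neighbors_ok(v, []):
                seed_v = v
                break
        if seed_v is None:
            stall += 1
            if stall > 5:
                break
            continue
        stall = 0
        strio[seed_v] = True
        count += 1
        recent = [seed_v]
        # bias the initial direction along the nucleus long axis (y)
        if rng.random() < params.walk_axis_bias:
            d = int(rng.choice(axis_dirs))
        else:
            d = int(rng.integers(6))
        v = seed_v
        for _step in range(params.max_tubule_length):
            if count >= target:
                break
            if rng.random() >= params.walk_persistence:
                d = int(rng.integers(6))
            tried = [d] + [int(x) for x in rng.permutation(6) if int(x) != d]
            moved = False
            for dd in tried:
                off = _STEPS6[dd]
                nv = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if not (0 <= nv[0] < shape[0] and 0 <= nv[1] < shape[1] and 0 <= nv[2] < shape[2]):
                    continue
                if not in_nucleus[nv] or strio[nv]:
                    continue
                # touching only the last two own voxels permits straight runs
                # and corners but can never complete a 2x2 cross-section
                if not neighbors_ok(nv, recent[-2:]):
                    continue
                if rng.random() >= pacc[nv]:
                    continue
                strio[nv] = True
                count += 1
                recent.append(nv)
                v = nv
                d = dd
                moved = True
                break
            if not moved:
                break
    return strio


def _build_gt_compartment(nuclei: np.ndarray, rng: np.random.Generator,
                          params: PhantomParams) -> np.ndarray:
    gt = np.zeros(nuclei.shape, dtype=np.int8)
    for lab in (CAUDATE_LEFT, CAUDATE_RIGHT, PUTAMEN_LEFT, PUTAMEN_RIGHT):
        mask = nuclei == lab
        n = int(mask.sum())
        target = int(round(params.striosome_fraction * n))
        strio = _grow_tubules(mask, target, rng, params)
        got = int(strio.sum())
        if abs(got - target) > params.fraction_tolerance * n:
            raise InfeasibleGeometryError(
                f"could not reach striosome fraction {params.striosome_fraction:.2f} "
                f"in nucleus label {lab} under the diameter cap "
                f"(placed {got} of {target} voxels)"
            )
        gt[mask] = MATRIX
        gt[strio] = STRIOSOME
    return gt


def _centroid_offset(gt: np.ndarray, grid: Grid) -> np.ndarray:
    """striosome centroid minus matrix centroid, world mm."""
    sc = grid.world(np.argwhere(gt == STRIOSOME)).mean(axis=0)
    mc = grid.world(np.argwhere(gt == MATRIX)).mean(axis=0)
    return sc - mc


def _check_gt(gt: np.ndarray, nuclei: np.ndarray, grid: Grid, params: PhantomParams) -> bool:
    off = _centroid_offset(gt, grid)
    if off[1] < params.min_centroid_offset_mm or off[2] > -params.min_centroid_offset_mm:
        return False
    for side, labs in (("left", (CAUDATE_LEFT, PUTAMEN_LEFT)),
                       ("right", (CAUDATE_RIGHT, PUTAMEN_RIGHT))):
        hemi_strio = (gt == STRIOSOME) & np.isin(nuclei, labs)
        _, n = labeled_components(hemi_strio, 26)
        if n < params.min_components_per_hemisphere:
            return False
    return True


# ---------------------------------------------------------------------------
# Orientation field
# ---------------------------------------------------------------------------


def _sector_ids(coords_flat: np.ndarray, origin: np.ndarray, sign: float) -> tuple[np.ndarray, np.ndarray]:
    """(matrix_sector, striosome_sector) per voxel by nearest wedge azimuth."""
    rel = coords_flat - origin
    azim = np.degrees(np.arctan2(rel[:, 0] * sign, rel[:, 1]))
    msec = np.argmin(
        np.abs(np.stack([_wrap_deg(azim - a) for a in _MATRIX_AZIMUTHS_DEG])), axis=0)
    ssec = np.argmin(
        np.abs(np.stack([_wrap_deg(azim - a) for a in _STRIO_AZIMUTHS_DEG])), axis=0)
    return msec, ssec


def _build_orientation(grid: Grid, params: PhantomParams, nuclei: np.ndarray,
                       gt: np.ndarray, atlas_masks: dict[str, np.ndarray],
                       centers: dict[str, dict[str, np.ndarray]],
                       conversions: list[Conversion]) -> OrientationField:
    K = 10
    dirs = np.zeros(grid.shape + (K, 3), dtype=np.float32)
    weights = np.zeros(grid.shape + (K,), dtype=np.float32)
    coords = grid.coords()

    region_mask_any = np.zeros(grid.shape, dtype=bool)
    for m in atlas_masks.values():
        region_mask_any |= m

    # effective wiring compartment: ground truth, overridden inside conversions
    wiring = gt.copy()
    for conv in conversions:
        sel = conv.zone & (gt == conv.from_compartment)
        wiring[sel] = conv.to_compartment

    for side, sign, labs in (("left", -1.0, (CAUDATE_LEFT, PUTAMEN_LEFT)),
                             ("right", 1.0, (CAUDATE_RIGHT, PUTAMEN_RIGHT))):
        hemi = np.isin(nuclei, labs)
        vox = np.argwhere(hemi)
        if len(vox) == 0:
            continue
        pos = grid.world(vox)
        centroid = hemisphere_centroid(params, side)
        msec, ssec = _sector_ids(pos, centroid, sign)
        # direction entries 0..4: matrix regions (vertical ascending fibers);
        # 5..9: striosome regions (horizontal fibers toward each wedge's aim
        # point).  Each entry is the local orientation of that region's
        # efferent fascicle where it passes through the voxel.
        for k, name in enumerate(MATRIX_REGIONS):
            dirs[vox[:, 0], vox[:, 1], vox[:, 2], k] = np.array(
                [0.0, 0.0, 1.0], dtype=np.float32)
        for k, name in enumerate(STRIOSOME_REGIONS):
            c = centers[name][side]
            d = c - pos
            d[:, 2] = 0.0
            d /= np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-9)
            dirs[vox[:, 0], vox[:, 1], vox[:, 2], 5 + k] = d.astype(np.float32)
        comp = wiring[vox[:, 0], vox[:, 1], vox[:, 2]]
        w = np.zeros((len(vox), K), dtype=np.float32)
        leak, zdom = params.leakage, params.zone_dominance
        own_major = (1.0 - leak) * zdom
        own_minor = (1.0 - leak) * (1.0 - zdom) / 4.0
        # the opposite-affinity mass rides the voxel's opposite-sector axis:
        # it is both the leakage route and the local through-fascicle that
        # lets opposite-committed streamlines traverse this voxel
        is_matrix = comp == MATRIX
        w[is_matrix, :5] = own_minor
        w[np.where(is_matrix)[0], msec[is_matrix]] = own_major
        w[np.where(is_matrix)[0], 5 + ssec[is_matrix]] = leak
        is_strio = ~is_matrix
        w[is_strio, 5:] = own_minor
        w[np.where(is_strio)[0], 5 + ssec[is_strio]] = own_major
        w[np.where(is_strio)[0], msec[is_strio]] = leak
        weights[vox[:, 0], vox[:, 1], vox[:, 2]] = w

    # corridor: every non-striatal voxel carries two smooth crossing
    # fascicles — a vertical one that rides dorsally committed (matrix-bound)
    # streamlines straight up into the polar cap, and a horizontal-radial one
    # that rides equatorially committed (striosome-bound) streamlines
    # outward into the equatorial band.  The curvature gate selects the
    # fascicle matching the streamline's committed fan; the other is always
    # near-perpendicular and rejected.
    corridor = ~(nuclei > 0)
    cv = np.argwhere(corridor)
    cpos = coords[corridor]
    centroids = {s: hemisphere_centroid(params, s) for s in ("left", "right")}
    side_of = np.where(cpos[:, 0] < 0.0, 0, 1)  # 0=left, 1=right
    hr = np.zeros_like(cpos)
    for s_idx, side in enumerate(("left", "right")):
        sel = side_of == s_idx
        if not sel.any():
            continue
        rel = cpos[sel] - centroids[side]
        rel[:, 2] = 0.0
        hr[sel] = rel / np.maximum(np.linalg.norm(rel, axis=1, keepdims=True), 1e-9)
    dirs[cv[:, 0], cv[:, 1], cv[:, 2], 0] = np.array([0.0, 0.0, 1.0], dtype=np.float32)
    dirs[cv[:, 0], cv[:, 1], cv[:, 2], 1] = hr.astype(np.float32)
    weights[cv[:, 0], cv[:, 1], cv[:, 2], 0] = 0.5
    weights[cv[:, 0], cv[:, 1], cv[:, 2], 1] = 0.5
    return OrientationField(grid, dirs, weights)


# ---------------------------------------------------------------------------
# Subject construction
# ---------------------------------------------------------------------------


def build_phantom(params: PhantomParams | None = None, rng_seed: int = 0, *,
                  subject_id: str = "phantom-000", group: str = "HC",
                  severity_score: float | None = None, scanner_id: str = "scanner_1",
                  study_id: str = "study_a", age: float = 30.0,
                  conversions: list[Conversion] | None = None,
                  putamen_scale: float = 1.0,
                  etiv_jitter: float = 1.0) -> PhantomSubject:
    """Build one phantom subject.

    ``conversions`` and ``putamen_scale`` implement group-level effects and
    are normally supplied by :func:`simulate_cohort`.
    """
    params = params or PhantomParams()
    params.validate()
    grid = params.grid
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(rng_seed)))

    nuclei = _rasterize_nuclei(grid, params, putamen_scale)
    gt = None
    for _attempt in range(params.max_geometry_retries):
        cand = _build_gt_compartment(nuclei, rng, params)
        if _check_gt(cand, nuclei, grid, params):
            gt = cand
            break
    if gt is None:
        raise InfeasibleGeometryError(
            "could not satisfy striosome centroid-offset / component-count "
            f"invariants in {params.max_geometry_retries} attempts"
        )

    centers = region_centers(params)
    masks = _rasterize_regions(grid, params, centers)
    orientation = _build_orientation(grid, params, nuclei, gt, masks, centers,
                                     list(conversions or []))

    # ground-truth somatotopic zones: per region, the same-affinity voxels of
    # the sector that the region dominates
    gt_zone: dict[str, np.ndarray] = {n: np.zeros(grid.shape, dtype=bool) for n in ALL_REGIONS}
    for side, sign, labs in (("left", -1.0, (CAUDATE_LEFT, PUTAMEN_LEFT)),
                             ("right", 1.0, (CAUDATE_RIGHT, PUTAMEN_RIGHT))):
        hemi = np.isin(nuclei, labs)
        vox = np.argwhere(hemi)
        msec, ssec = _sector_ids(grid.world(vox), hemisphere_centroid(params, side), sign)
        comp = gt[vox[:, 0], vox[:, 1], vox[:, 2]]
        for i, name in enumerate(MATRIX_REGIONS):
            sel = vox[(msec == i) & (comp == MATRIX)]
            gt_zone[name][sel[:, 0], sel[:, 1], sel[:, 2]] = True
        for i, name in enumerate(STRIOSOME_REGIONS):
            sel = vox[(ssec == i) & (comp == STRIOSOME)]
            gt_zone[name][sel[:, 0], sel[:, 1], sel[:, 2]] = True

    affinity = {n: "matrix" for n in MATRIX_REGIONS}
    affinity.update({n: "striosome" for n in STRIOSOME_REGIONS})
    atlas = BaitAtlas(regions=masks, affinity=affinity, gt_zone=gt_zone, centers=centers)

    # diffusion eigenvalue triples on striatal voxels, shared subject factor
    rd_field = np.zeros(grid.shape + (3,), dtype=np.float32)
    striatal = nuclei > 0
    lam = np.array(params.base_eigenvalues)
    factor = np.exp(rng.normal(0.0, 0.05, size=int(striatal.sum())))
    rd_field[striatal] = (lam[None, :] * factor[:, None]).astype(np.float32)

    return PhantomSubject(
        subject_id=subject_id, params=params, nuclei=nuclei, gt_compartment=gt,
        orientation=orientation, bait_atlas=atlas, rd_field=rd_field,
        etiv=float(params.etiv_mm3 * etiv_jitter), group=group,
        severity_score=severity_score, scanner_id=scanner_id, study_id=study_id,
        age=age,
    )


# ---------------------------------------------------------------------------
# Severity categorization
# ---------------------------------------------------------------------------

_SEVERITY_BINS = {
    # scale -> (lower edges for Mild/Moderate/Severe/VerySevere, upper cap)
    "hamilton": (8.0, 14.0, 19.0, 23.0, math.inf),
    "rcads": (18.0, 21.0, 24.0, 27.0, math.inf),
    "achenbach": (70.0, 78.0, 85.0, 92.0, 100.0),
}
SEVERITY_CATEGORIES = ("BelowThreshold", "Mild", "Moderate", "Severe", "VerySevere")


def severity_to_category(scale: str, score: float) -> str:
    """Bin a depression-scale score into a severity category.

    Hamilton: 8–13 mild, 14–18 moderate, 19–22 severe, >22 very severe.
    RCADS and Achenbach analogously; interval edges that appear in two
    printed bins are resolved as half-open intervals (lower bin excludes its
    upper edge).  Scores below the lowest bin map to ``BelowThreshold``.
    """
    if not math.isfinite(score):
        raise ValueError("severity score must be finite")
    key = scale.lower()
    if key not in _SEVERITY_BINS:
        raise ValueError(f"unknown severity scale {scale!r}")
    mild, moderate, severe, very, cap = _SEVERITY_BINS[key]
    if score < mild or score > cap:
        return "BelowThreshold"
    if score < moderate:
        return "Mild"
    if score < severe:
        return "Moderate"
    if score < very:
        return "Severe"
    return "VerySevere"


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """A simulated MDD/HC cohort.

    ``effects`` holds multiplicative shifts of compartment-like volume in the
    MDD group, per nucleus: the defaults shrink putamen matrix-like volume by
    8.2% and grow striosome-like volume by 15%.  Internally each nucleus pair
    is realized as (a) a localized rewiring zone whose size is solved from
    the two shifts and (b) an overall nucleus volume scaling.
    ``severity_gradient`` converts that fraction of caudate striosome wiring
    to matrix wiring per severity point above the Hamilton threshold (8).
    """

    n_mdd: int = 20
    n_hc: int = 20
    match_ratio: int = 1
    effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"putamen": {"matrix": -0.082, "striosome": 0.15}}
    )
    severity_gradient: float = 0.015
    hemispheric_asymmetry: float = 0.0
    rng_seed: int = 0
    subject_jitter_sigma: float = 0.03
    phantom: PhantomParams = field(default_factory=PhantomParams)

    def validate(self) -> None:
        if self.n_mdd < 1 or self.n_hc < 1:
            raise ValueError("cohort group sizes must be >= 1")
        if self.n_hc != self.n_mdd * self.match_ratio:
            raise ValueError("n_hc must equal n_mdd * match_ratio")
        for nucleus, eff in self.effects.items():
            for v in eff.values():
                if not math.isfinite(v):
                    raise ValueError(f"non-finite effect for {nucleus}")


def _solve_effect(matrix_shift: float, striosome_shift: float,
                  matrix_striosome_ratio: float) -> tuple[float, float]:
    """Solve (conversion fraction f, volume scale s) from target shifts.

    Matrix-like volume scales as s*(1-f) and striosome-like as
    s*(1 + f*r) with r the matrix:striosome ground-truth volume ratio.
    """
    a = 1.0 + matrix_shift
    b = 1.0 + striosome_shift
    r = matrix_striosome_ratio
    f = (b / a - 1.0) / (r + b / a)
    s = a / (1.0 - f)
    return f, s


def _zone_mask(grid: Grid, nucleus_mask: np.ndarray, anchor: np.ndarray, n_vox: int) -> np.ndarray:
    """The n_vox nucleus voxels nearest to a world anchor point."""
    vox = np.argwhere(nucleus_mask)
    d2 = ((grid.world(vox) - anchor) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")[:n_vox]
    out = np.zeros(grid.shape, dtype=bool)
    sel = vox[order]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return out


def cohort_effect_zones(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Ground-truth masks of the regions where MDD effects are injected."""
    params = spec.phantom
    grid = params.grid
    nuclei = _rasterize_nuclei(grid, params)
    zones: dict[str, np.ndarray] = {}
    fraction_r = (1.0 - params.striosome_fraction) / params.striosome_fraction
    for nucleus, eff in spec.effects.items():
        f, _s = _solve_effect(eff.get("matrix", 0.0), eff.get("striosome", 0.0), fraction_r)
        if abs(f) < 1e-12:
            continue
        mask = np.isin(nuclei, [NUCLEUS_LABELS[f"{nucleus}_left"],
                                NUCLEUS_LABELS[f"{nucleus}_right"]])
        zone = np.zeros(grid.shape, dtype=bool)
        for sign in (-1.0, 1.0):
            anchor = _rostral_anchor(params, nucleus) * np.array([sign, 1.0, 1.0])
            hemi = mask & (grid.coords()[..., 0] * sign >= 0)
            n_hemi = int(round(abs(f) * hemi.sum()))
            zone |= _zone_mask(grid, hemi, anchor, n_hemi)
        zones[nucleus] = zone
    if spec.severity_gradient:
        mask = np.isin(nuclei, [CAUDATE_LEFT, CAUDATE_RIGHT])
        zone = np.zeros(grid.shape, dtype=bool)
        max_frac = min(0.9, spec.severity_gradient * 22.0)  # Hamilton range 8..30
        for sign in (-1.0, 1.0):
            anchor = _rostral_anchor(params, "caudate") * np.array([sign, 1.0, 1.0])
            hemi = mask & (grid.coords()[..., 0] * sign >= 0)
            zone |= _zone_mask(grid, hemi, anchor, int(round(max_frac * hemi.sum())))
        zones["caudate_severity"] = zone
    return zones


def _rostral_anchor(params: PhantomParams, nucleus: str) -> np.ndarray:
    if nucleus == "putamen":
        c = np.array(params.putamen_center)
        return c + np.array([0.0, params.putamen_radii[1] * 0.7, 0.0])
    c = np.array(params.caudate_center)
    return c + np.array([0.0, params.caudate_radii[1] * 0.7, -params.caudate_radii[2] * 0.2])


def cohort_manifest(spec: CohortSpec) -> pd.DataFrame:
    """Subject manifest (group, severity, eTIV, scanner, study, age).

    Deterministic in ``spec.rng_seed``; geometry is not built here.
    """
    spec.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.rng_seed, 9001])))
    rows = []
    studies = ("study_a", "study_b")
    scanners = ("scanner_1", "scanner_2")
    n_total = spec.n_mdd + spec.n_hc
    groups = ["MDD"] * spec.n_mdd + ["HC"] * spec.n_hc
    for i in range(n_total):
        group = groups[i]
        block = i % spec.n_mdd if group == "MDD" else (i - spec.n_mdd) % spec.n_mdd
        score = float(rng.integers(8, 31)) if group == "MDD" else None
        rows.append({
            "subject_id": f"sub-{i:03d}",
            "group": group,
            "severity_score": score,
            "severity_category": severity_to_category("hamilton", score) if score is not None else "",
            "scale": "hamilton" if score is not None else "",
            "etiv_jitter": float(np.exp(rng.normal(0.0, spec.subject_jitter_sigma))),
            "volume_jitter": float(np.exp(rng.normal(0.0, spec.subject_jitter_sigma))),
            "scanner_id": scanners[block % 2],
            "study_id": studies[(block // 2) % 2],
            "age": float(np.round(rng.uniform(18.0, 45.0), 1)),
            "phantom_seed": int(rng.integers(0, 2**31 - 1)),
        })
    df = pd.DataFrame(rows)
    return df


def build_cohort_subject(spec: CohortSpec, row: pd.Series) -> PhantomSubject:
    """Build one cohort member from its manifest row."""
    params = spec.phantom
    grid = params.grid
    fraction_r = (1.0 - params.striosome_fraction) / params.striosome_fraction
    conversions: list[Conversion] = []
    putamen_scale = 1.0
    if row["group"] == "MDD":
        zones = cohort_effect_zones(spec)
        for nucleus, eff in spec.effects.items():
            f, s = _solve_effect(eff.get("matrix", 0.0), eff.get("striosome", 0.0), fraction_r)
            if nucleus == "putamen":
                putamen_scale = s
            if abs(f) > 1e-12 and nucleus in zones:
                src, dst = (MATRIX, STRIOSOME) if f > 0 else (STRIOSOME, MATRIX)
                conversions.append(Conversion(zones[nucleus], src, dst))
        if spec.severity_gradient and row["severity_score"] is not None:
            sev_zone = zones.get("caudate_severity")
            if sev_zone is not None:
                frac = min(0.9, spec.severity_gradient * max(float(row["severity_score"]) - 8.0, 0.0))
                max_frac = min(0.9, spec.severity_gradient * 22.0)
                nuclei = _rasterize_nuclei(grid, params)
                caud = np.isin(nuclei, [CAUDATE_LEFT, CAUDATE_RIGHT])
                zone = np.zeros(grid.shape, dtype=bool)
                for sign in (-1.0, 1.0):
                    anchor = _rostral_anchor(params, "caudate") * np.array([sign, 1.0, 1.0])
                    hemi = caud & (grid.coords()[..., 0] * sign >= 0)
                    n = int(round(frac / max(max_frac, 1e-9) * (sev_zone & hemi).sum()))
                    zone |= _zone_mask(grid, hemi, anchor, n)
                conversions.append(Conversion(zone, STRIOSOME, MATRIX))
                if spec.hemispheric_asymmetry:
                    right = grid.coords()[..., 0] >= 0
                    extra = _zone_mask(grid, caud & right,
                                       _rostral_anchor(params, "caudate"),
                                       int(round(spec.hemispheric_asymmetry * (caud & right).sum())))
                    conversions.append(Conversion(extra, STRIOSOME, MATRIX))
    return build_phantom(
        params, rng_seed=int(row["phantom_seed"]), subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        severity_score=None if row["severity_score"] is None or row["severity_score"] != row["severity_score"] else float(row["severity_score"]),
        scanner_id=str(row["scanner_id"]), study_id=str(row["study_id"]),
        age=float(row["age"]), conversions=conversions,
        putamen_scale=putamen_scale * float(row["volume_jitter"]),
        etiv_jitter=float(row["etiv_jitter"]),
    )


def iter_cohort(spec: CohortSpec):
    """Yield (manifest row, PhantomSubject) one subject at a time."""
    manifest = cohort_manifest(spec)
    for _, row in manifest.iterrows():
        yield row, build_cohort_subject(spec, row)


def simulate_cohort(spec: CohortSpec) -> tuple[list[PhantomSubject], pd.DataFrame]:
    """Materialize the full cohort (prefer :func:`iter_cohort` for large n)."""
    manifest = cohort_manifest(spec)
    subjects = [build_cohort_subject(spec, row) for _, row in manifest.iterrows()]
    return subjects, manifest
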