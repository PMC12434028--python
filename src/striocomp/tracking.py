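"""Simplified probabilistic streamline tracking over orientation fields.

Two modes mirror the two tractography configurations of the analysis:

* :func:`track_classification` — every seed voxel launches a fixed number of
  streamlines and each is credited to the first target mask it touches
  (classification-targets counting);
* :func:`track_streamline_mode` — a whole seed region launches streamlines
  that must touch a target/waypoint and never touch an avoid mask; the
  success count is normalized by the seed-mask volume.

Propagation: a streamline starts at a uniformly jittered position inside its
seed voxel, samples a direction from the local mixture (first step taken as
drawn), then repeatedly steps a fixed length and re-samples.  A re-sampled
direction is antipodally flipped when the flip better matches the previous
step; it is accepted when the cosine with the previous direction reaches the
curvature threshold, re-drawn up to a bounded retry count otherwise, and the
streamline is discarded when no compatible direction is found, when it exits
the defined field or grid, enters the exclusion mask, or exhausts its step
budget.  Field lookup is nearest-voxel (phantom fields are piecewise
constant); real-data trackers typically interpolate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .grid import OrientationField


@dataclass(frozen=True)
class TrackingParams:
    """Streamline propagation parameters (defaults follow common
    probabilistic-tractography settings: cos-curvature 0.2, 0.5 mm steps,
    2,000 steps and 5,000 samples per seed voxel)."""

    curvature_threshold: float = 0.2
    step_length_mm: float = 0.5
    max_steps: int = 2000
    samples_per_seed_voxel: int = 5000
    rng_seed: int = 0
    #: re-draws allowed when a sample violates curvature; enough retries act
    #: as a crossing-fiber selector (the compatible mixture component is
    #: found with high probability before the streamline is discarded)
    curvature_retries: int = 16
    #: treat drawn directions as sign-ambiguous after the first step
    antipodal: bool = True

    def validate(self) -> None:
        if not (-1.0 <= self.curvature_threshold <= 1.0):
            raise ValueError("curvature_threshold must lie in [-1, 1]")
        if self.step_length_mm <= 0:
            raise ValueError("step_length_mm must be > 0")
        if self.max_steps < 1 or self.samples_per_seed_voxel < 1:
            raise ValueError("max_steps and samples_per_seed_voxel must be >= 1")


@dataclass
class StreamlineCounts:
    """Per-seed-voxel first-touch streamline counts."""

    seed_voxels: np.ndarray          # (n_seeds, 3) int
    target_names: tuple[str, ...]
    counts: np.ndarray               # (n_seeds, n_targets) int64
    launched: int                    # streamlines launched per voxel
    voxel_volume_mm3: float

    def count_grid(self, shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
        """Counts as one 3D volume per target."""
        out = {}
        i, j, k = self.seed_voxels.T
        for t, name in enumerate(self.target_names):
            vol = np.zeros(shape, dtype=np.int64)
            vol[i, j, k] = self.counts[:, t]
            out[name] = vol
        return out

    def normalized_totals(self) -> dict[str, float]:
        """Per-target totals divided by the seed-mask volume in mm^3."""
        seed_volume = len(self.seed_voxels) * self.voxel_volume_mm3
        return {
            name: float(self.counts[:, t].sum()) / seed_volume
            for t, name in enumerate(self.target_names)
        }


@njit(cache=True)
def _propagate(dirs, weights, target_label, exclusion, waypoint, seeds, samples,
               step_vox, curvature, max_steps, retries, antipodal, require_waypoint,
               random_init_sign, rng_seed):  # pragma: no cover - exercised through wrappers
    np.random.seed(rng_seed)
    n_seeds = seeds.shape[0]
    n_targets = int(target_label.max())
    counts = np.zeros((n_seeds, max(n_targets, 1)), dtype=np.int64)
    nx, ny, nz, K = weights.shape
    for si in range(n_seeds):
        s0, s1, s2 = seeds[si, 0], seeds[si, 1], seeds[si, 2]
        for _ in range(samples):
            px = s0 + np.random.random()
            py = s1 + np.random.random()
            pz = s2 + np.random.random()
            # initial direction: categorical draw at the seed voxel, as drawn
            wsum = 0.0
            for k in range(K):
                wsum += weights[s0, s1, s2, k]
            if wsum <= 0.0:
                continue
            r = np.random.random() * wsum
            acc = 0.0
            kk = K - 1
            for k in range(K):
                acc += weights[s0, s1, s2, k]
                if r < acc:
                    kk = k
                    break
            dx = dirs[s0, s1, s2, kk, 0]
            dy = dirs[s0, s1, s2, kk, 1]
            dz = dirs[s0, s1, s2, kk, 2]
            if random_init_sign and np.random.random() < 0.5:
                dx, dy, dz = -dx, -dy, -dz
            touched_waypoint = not require_waypoint
            ci, cj, cl = s0, s1, s2
            for _step in range(max_steps):
                px += dx * step_vox
                py += dy * step_vox
                pz += dz * step_vox
                i = int(np.floor(px))
                j = int(np.floor(py))
                l = int(np.floor(pz))
                if i < 0 or j < 0 or l < 0 or i >= nx or j >= ny or l >= nz:
                    break
                if exclusion[i, j, l]:
                    break
                if require_waypoint and waypoint[i, j, l]:
                    touched_waypoint = True
                t = target_label[i, j, l]
                if t > 0:
                    if touched_waypoint:
                        counts[si, t - 1] += 1
                    break
                if i == ci and j == cj and l == cl:
                    # fields are piecewise constant per voxel: re-sampling is
                    # only informative when the streamline enters a new voxel
                    continue
                ci, cj, cl = i, j, l
                # re-sample direction at the newly entered voxel
                wsum = 0.0
                for k in range(K):
                    wsum += weights[i, j, l, k]
                if wsum <= 0.0:
                    break
                ok = False
                for _try in range(retries + 1):
                    r = np.random.random() * wsum
                    acc = 0.0
                    kk = K - 1
                    for k in range(K):
                        acc += weights[i, j, l, k]
                        if r < acc:
                            kk = k
                            break
                    ndx = dirs[i, j, l, kk, 0]
                    ndy = dirs[i, j, l, kk, 1]
                    ndz = dirs[i, j, l, kk, 2]
                    dp = ndx * dx + ndy * dy + ndz * dz
                    if antipodal and dp < 0.0:
                        ndx, ndy, ndz, dp = -ndx, -ndy, -ndz, -dp
                    if dp >= curvature:
                        dx, dy, dz = ndx, ndy, ndz
                        ok = True
                        break
                if not ok:
                    break
    return counts


def _as_label_volume(target_masks: dict[str, np.ndarray]) -> tuple[np.ndarray, tuple[str, ...]]:
    names = tuple(target_masks)
    first = target_masks[names[0]]
    label = np.zeros(first.shape, dtype=np.int16)
    for t, name in enumerate(names):
        mask = target_masks[name]
        if (label[mask] != 0).any():
            raise ValueError(f"target mask {name!r} overlaps another target")
        label[mask] = t + 1
    return label, names


def track_classification(field: OrientationField, seed_mask: np.ndarray,
                         target_masks: dict[str, np.ndarray],
                         exclusion_mask: np.ndarray | None,
                         params: TrackingParams) -> StreamlineCounts:
    """Classification-targets tracking: per-voxel first-touch target counts."""
    params.validate()
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    if not field.defined_mask[seed_mask].all():
        raise ValueError("seed voxels must lie inside the defined orientation field")
    label, names = _as_label_volume(target_masks)
    if (label[seed_mask] != 0).any():
        raise ValueError("target masks must be disjoint from the seed mask")
    if exclusion_mask is None:
        exclusion_mask = np.zeros(seed_mask.shape, dtype=bool)
    if (label[exclusion_mask] != 0).any():
        raise ValueError("target masks must be disjoint from the exclusion mask")
    seeds = np.ascontiguousarray(np.argwhere(seed_mask).astype(np.int64))
    counts = _propagate(
        field.dirs, field.weights, label, np.ascontiguousarray(exclusion_mask),
        np.zeros(seed_mask.shape, dtype=bool), seeds,
        int(params.samples_per_seed_voxel),
        float(params.step_length_mm / field.grid.voxel_size),
        float(params.curvature_threshold), int(params.max_steps),
        int(params.curvature_retries), params.antipodal, False, False,
        _kernel_seed(params.rng_seed),
    )
    return StreamlineCounts(seeds, names, counts[:, : len(names)],
                            params.samples_per_seed_voxel, field.grid.voxel_volume)


def track_streamline_mode(field: OrientationField, seed_region: np.ndarray,
                          target_region: np.ndarray,
                          waypoint_mask: np.ndarray | None,
                          avoid_mask: np.ndarray | None,
                          params: TrackingParams) -> float:
    """Region-to-region streamline count normalized by seed volume (mm^-3).

    A streamline succeeds when it reaches ``target_region`` having passed
    through ``waypoint_mask`` (if given) and never touched ``avoid_mask``.
    Samples launch in a randomly chosen orientation (orientation fields are
    sign-ambiguous; seeding is two-directional as in streamline tractography).
    """
    params.validate()
    if not seed_region.any():
        raise ValueError("seed region is empty")
    masks = [seed_region, target_region]
    if waypoint_mask is not None:
        masks.append(waypoint_mask)
    if avoid_mask is not None:
        masks.append(avoid_mask)
    for a in range(len(masks)):
        for b in range(a + 1, len(masks)):
            if (masks[a] & masks[b]).any():
                raise ValueError("seed/target/waypoint/avoid masks must be mutually disjoint")
    label = np.zeros(seed_region.shape, dtype=np.int16)
    label[target_region] = 1
    avoid = avoid_mask if avoid_mask is not None else np.zeros(seed_region.shape, dtype=bool)
    waypoint = waypoint_mask if waypoint_mask is not None else np.zeros(seed_region.shape, dtype=bool)
    seeds = np.ascontiguousarray(np.argwhere(seed_region).astype(np.int64))
    counts = _propagate(
        field.dirs, field.weights, label, np.ascontiguousarray(avoid),
        np.ascontiguousarray(waypoint), seeds,
        int(params.samples_per_seed_voxel),
        float(params.step_length_mm / field.grid.voxel_size),
        float(params.curvature_threshold), int(params.max_steps),
        int(params.curvature_retries), params.antipodal, waypoint_mask is not None,
        True, _kernel_seed(params.rng_seed),
    )
    seed_volume = len(seeds) * field.grid.voxel_volume
    return float(counts.sum()) / seed_volume


def _kernel_seed(seed: int) -> int:
    """Fold an arbitrary integer seed into the kernel RNG range."""
    return int(np.random.SeedSequence(seed).generate_state(1, np.uint32)[0] % (2**31 - 1))
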