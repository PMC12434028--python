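"""End-to-end orchestration: phantom -> tracking -> parcellation -> measures
-> somatotopy -> group inference.

Tracking is always run per hemisphere with a contra-hemispheric exclusion
mask; hemispheres are recombined before voxelwise group inference.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import phantom as ph
from .grid import Grid
from .inference import (TFCEParams, PermutationResult, association_test, bh_adjust,
                        cluster_descriptors, group_compare, permutation_test)
from .parcellation import (MATRIX_LIKE, STRIOSOME_LIKE, CompartmentParcellation,
                           HighBiasMasks, ProbabilityMaps, build_high_bias_masks,
                           centroid_relative_locations, classify_voxels,
                           compartment_volumes, compute_bias_probabilities,
                           largest_cluster_volume, radial_diffusivity)
from .somatotopy import (SomatotopicZoneSet, compute_influence_maps, derive_zones,
                         n_minus_one_parcellation, zone_ratio_table)
from .tracking import StreamlineCounts, TrackingParams, track_classification

HEMISPHERES = ("left", "right")
_HEMI_LABELS = {
    "left": (ph.CAUDATE_LEFT, ph.PUTAMEN_LEFT),
    "right": (ph.CAUDATE_RIGHT, ph.PUTAMEN_RIGHT),
}


def _hemi_seed(base_seed: int, side: str, leave_out: str | None) -> int:
    """Derive a per-hemisphere kernel seed; the stream is identical for the
    full and every N-1 parcellation so the runs are comparable."""
    h = 0 if side == "left" else 1
    return int(np.random.SeedSequence([int(base_seed), h]).generate_state(1)[0] % (2**31 - 1))


def subject_probability_maps(subject: ph.PhantomSubject, params: TrackingParams,
                             min_total_count: int = 10,
                             leave_out: str | None = None) -> ProbabilityMaps:
    """Classification-targets tractography for both hemispheres, merged into
    compartment-bias probability maps (optionally with one bait region left
    out of its composite)."""
    grid = subject.grid
    atlas = subject.bait_atlas
    per_hemi: list[StreamlineCounts] = []
    for side in HEMISPHERES:
        hemi = grid.hemisphere_mask(side)
        contra = grid.hemisphere_mask("right" if side == "left" else "left")
        seeds = np.isin(subject.nuclei, _HEMI_LABELS[side])
        targets = {
            "matrix": atlas.composite("matrix", hemi),
            "striosome": atlas.composite("striosome", hemi),
        }
        if leave_out is not None:
            aff = atlas.affinity[leave_out]
            targets[aff] = targets[aff] & ~atlas.regions[leave_out]
        hemi_params = replace(params, rng_seed=_hemi_seed(params.rng_seed, side, leave_out))
        per_hemi.append(track_classification(subject.orientation, seeds, targets,
                                             contra, hemi_params))
    return compute_bias_probabilities(per_hemi, subject.striatal_mask, grid,
                                      min_total_count)


@dataclass
class SubjectParcellation:
    """All per-subject parcellation outputs."""

    subject_id: str
    prob: ProbabilityMaps
    parcellation: CompartmentParcellation
    high_bias: HighBiasMasks
    volumes: pd.DataFrame
    measures: dict[str, float]


def parcellate_subject(subject: ph.PhantomSubject, tracking: TrackingParams,
                       bias_threshold: float = 0.55, min_total_count: int = 10,
                       target_fraction: float = 0.13,
                       cluster_connectivity: int = 26) -> SubjectParcellation:
    """Run the full single-subject pipeline and assemble its measures."""
    prob = subject_probability_maps(subject, tracking, min_total_count)
    parc = classify_voxels(prob, bias_threshold)
    high_bias = build_high_bias_masks(prob, subject.striatal_mask, target_fraction)
    nucleus_labels = {
        "caudate": [ph.CAUDATE_LEFT, ph.CAUDATE_RIGHT],
        "putamen": [ph.PUTAMEN_LEFT, ph.PUTAMEN_RIGHT],
    }
    volumes = compartment_volumes(parc, subject.nuclei, subject.etiv, nucleus_labels)
    grid = subject.grid
    vv = grid.voxel_volume

    measures: dict[str, float] = {"etiv_mm3": subject.etiv}
    for nucleus, labs in nucleus_labels.items():
        nmask = np.isin(subject.nuclei, labs)
        raw = float(nmask.sum()) * vv
        measures[f"{nucleus}_volume_mm3"] = raw
        measures[f"{nucleus}_volume_norm"] = raw / subject.etiv
        measures[f"{nucleus}_rd"] = radial_diffusivity(subject.rd_field, nmask)
        for plab, pname in ((MATRIX_LIKE, "matrix_like"), (STRIOSOME_LIKE, "striosome_like")):
            r = float((nmask & (parc.labels == plab)).sum()) * vv
            measures[f"{nucleus}_{pname}_mm3"] = r
            measures[f"{nucleus}_{pname}_norm"] = r / subject.etiv
    measures["largest_matrix_cluster_mm3"] = largest_cluster_volume(
        parc.labels == MATRIX_LIKE, vv, cluster_connectivity)
    measures["largest_striosome_cluster_mm3"] = largest_cluster_volume(
        parc.labels == STRIOSOME_LIKE, vv, cluster_connectivity)
    measures["matrix_highbias_rd"] = radial_diffusivity(subject.rd_field,
                                                        high_bias.matrix_mask)
    measures["striosome_highbias_rd"] = radial_diffusivity(subject.rd_field,
                                                           high_bias.striosome_mask)
    # centroid-relative locations of the high-bias masks, pooled over nuclei
    offsets = {"matrix": [], "striosome": []}
    for nucleus, labs in nucleus_labels.items():
        nmask = np.isin(subject.nuclei, labs)
        for key, hb in (("matrix", high_bias.matrix_mask),
                        ("striosome", high_bias.striosome_mask)):
            sel = hb & nmask
            if sel.any():
                off = centroid_relative_locations(sel, nmask, grid)
                offsets[key].append((off, int(sel.sum())))
    for key, items in offsets.items():
        if items:
            w = np.array([n for _, n in items], dtype=float)
            mean = np.average(np.array([o for o, _ in items]), axis=0, weights=w)
            for ax, name in enumerate(("x", "y", "z")):
                measures[f"{key}_highbias_offset_{name}_mm"] = float(mean[ax])
    return SubjectParcellation(subject.subject_id, prob, parc, high_bias,
                               volumes, measures)


@dataclass
class SomatotopyResult:
    zone_set: SomatotopicZoneSet
    ratios: pd.DataFrame
    influence: dict


def somatotopic_analysis(subject: ph.PhantomSubject, tracking: TrackingParams,
                         min_total_count: int = 10, bias_threshold: float = 0.55,
                         floor_percentile: float = 75.0,
                         size_bound: float = 4.0) -> SomatotopyResult:
    """Full N-1 procedure: ten re-parcellations, influence maps, zones and
    per-zone compartment volume ratios."""
    full = subject_probability_maps(subject, tracking, min_total_count)
    n1 = {region: n_minus_one_parcellation(subject, region, tracking, min_total_count)
          for region in ph.ALL_REGIONS}
    influence = compute_influence_maps(full, n1)
    zone_set = derive_zones(influence, floor_percentile, size_bound,
                            striatal_mask=subject.striatal_mask)
    parc = classify_voxels(full, bias_threshold)
    ratios = zone_ratio_table(parc, zone_set, subject.bait_atlas.affinity)
    return SomatotopyResult(zone_set, ratios, influence)


# ---------------------------------------------------------------------------
# Cohort-level analysis
# ---------------------------------------------------------------------------

#: the pre-declared test families for BH correction
MEASURE_FAMILIES = {
    "nuclei_size": ("caudate_volume_norm", "putamen_volume_norm"),
    "nuclei_rd": ("caudate_rd", "putamen_rd"),
    "compartment_volumes": (
        "putamen_matrix_like_norm", "putamen_striosome_like_norm",
        "caudate_matrix_like_norm", "caudate_striosome_like_norm",
    ),
    "highbias_rd": ("matrix_highbias_rd", "striosome_highbias_rd"),
}
SEVERITY_FAMILY = ("caudate_matrix_like_norm", "caudate_striosome_like_norm")


@dataclass
class CohortAnalysis:
    """Group-level outputs of a simulated cohort."""

    manifest: pd.DataFrame
    measures: pd.DataFrame
    group_stats: pd.DataFrame
    severity_stats: pd.DataFrame
    permutation: dict[str, PermutationResult]
    clusters: dict[str, pd.DataFrame]
    common_mask: np.ndarray
    grid: Grid


def cohort_measures(spec: ph.CohortSpec, tracking: TrackingParams,
                    min_total_count: int = 10, bias_threshold: float = 0.55,
                    target_fraction: float = 0.13,
                    keep_maps: bool = True):
    """Parcellate every cohort member (built one at a time to bound memory).

    Returns (manifest, measures table, stacked p_matrix maps or None,
    common striatal mask, grid).
    """
    manifest = ph.cohort_manifest(spec)
    rows = []
    maps = []
    common = None
    grid = spec.phantom.grid
    for _, row in manifest.iterrows():
        subject = ph.build_cohort_subject(spec, row)
        sp = parcellate_subject(subject, tracking, bias_threshold, min_total_count,
                                target_fraction)
        rec = dict(row)
        rec.update(sp.measures)
        rows.append(rec)
        if keep_maps:
            maps.append(sp.prob.p_matrix.astype(np.float32))
            m = subject.striatal_mask & sp.prob.seeded_mask
            common = m if common is None else (common & m)
    measures = pd.DataFrame(rows)
    stacked = np.stack(maps) if keep_maps else None
    return manifest, measures, stacked, common, grid


def cohort_analysis(spec: ph.CohortSpec, tracking: TrackingParams,
                    n_perm: int = 1000, variance_smoothing_mm: float = 2.0,
                    tfce_params: TFCEParams | None = None, alpha: float = 0.05,
                    min_total_count: int = 10, bias_threshold: float = 0.55,
                    target_fraction: float = 0.13,
                    covariates: tuple[str, ...] = ("study_id", "scanner_id", "age"),
                    rng_seed: int = 0) -> CohortAnalysis:
    """The full group analysis of a simulated cohort.

    Scalar measures are compared with covariate-adjusted linear models and
    BH-corrected within the pre-declared families; voxelwise compartment
    bias is tested with Freedman-Lane permutations + TFCE for the MDD-vs-HC
    contrast (both directions) and, within the MDD subset, for the severity
    association.
    """
    if spec.n_mdd < 2 or spec.n_hc < 2:
        raise ValueError("need at least 2 subjects per group")
    manifest, measures, maps, common, grid = cohort_measures(
        spec, tracking, min_total_count, bias_threshold, target_fraction)

    stats_rows = []
    for family, outcomes in MEASURE_FAMILIES.items():
        results = [group_compare(measures, o, covariates=covariates) for o in outcomes]
        adj = bh_adjust([r.p_value for r in results], family)
        for r, (_, arow) in zip(results, adj.iterrows()):
            stats_rows.append({
                "family": family, "outcome": r.outcome, "F": r.f_statistic,
                "p": r.p_value, "bh_adjusted": arow["bh_adjusted"],
                "discovery": bool(arow["discovery"]),
                "percent_difference": r.percent_difference, "direction": r.direction,
            })
    group_stats = pd.DataFrame(stats_rows)

    from .inference import build_design
    mdd = measures[measures["group"] == "MDD"].copy()
    sev_rows = []
    mdd_supports_model = (
        len(mdd) >= 4 and mdd["severity_score"].notna().all()
        and len(mdd) - (build_design(mdd, covariates).shape[1] + 1) > 0
    )
    if mdd_supports_model:
        results = [association_test(mdd, o, "severity_score",
                                    covariates=tuple(c for c in covariates))
                   for o in SEVERITY_FAMILY]
        adj = bh_adjust([r.p_value for r in results], "severity_caudate")
        for r, (_, arow) in zip(results, adj.iterrows()):
            sev_rows.append({
                "family": "severity_caudate", "outcome": r.outcome,
                "slope": r.slope, "F": r.f_statistic, "p": r.p_value,
                "bh_adjusted": arow["bh_adjusted"],
                "discovery": bool(arow["discovery"]),
            })
    severity_stats = pd.DataFrame(sev_rows)

    # voxelwise permutation inference on the matrix-bias maps; computed on
    # the striatal bounding box (TFCE labelling scales with grid size) and
    # re-embedded into the full grid afterwards
    from .inference import build_design
    Z = build_design(manifest, covariates)[:, 1:]  # intercept added inside
    group_ind = (manifest["group"] == "MDD").to_numpy(float)
    cmaps, cmask, cgrid, bbox = _crop_to_mask(maps, common, grid)
    permutation: dict[str, PermutationResult] = {}
    clusters: dict[str, pd.DataFrame] = {}
    seeds = np.random.SeedSequence(rng_seed).generate_state(3) % (2**31 - 1)
    contrasts = {
        # MDD shift toward striosome-like bias: HC - MDD on p_matrix
        "group_striosome_shift": (cmaps, 1.0 - group_ind, Z, int(seeds[0])),
        "group_matrix_shift": (cmaps, group_ind, Z, int(seeds[1])),
    }
    for name, (m, reg, zz, sd) in contrasts.items():
        res = permutation_test(m, cmask, reg, zz, cgrid, n_perm,
                               variance_smoothing_mm, tfce_params, rng_seed=sd)
        clusters[name] = cluster_descriptors(res.corrected_p, cmask, cgrid, alpha)
        permutation[name] = _embed_result(res, grid, common, bbox)
    mdd_idx = np.flatnonzero(group_ind > 0.5)
    if len(mdd_idx) >= 8 and manifest.loc[mdd_idx, "severity_score"].notna().all():
        Z_mdd = build_design(manifest.iloc[mdd_idx], covariates)[:, 1:]
        sev = manifest.loc[mdd_idx, "severity_score"].to_numpy(float)
        res = permutation_test(cmaps[mdd_idx], cmask, sev, Z_mdd, cgrid, n_perm,
                               variance_smoothing_mm, tfce_params,
                               rng_seed=int(seeds[2]))
        clusters["severity_matrix_shift"] = cluster_descriptors(
            res.corrected_p, cmask, cgrid, alpha)
        permutation["severity_matrix_shift"] = _embed_result(res, grid, common, bbox)
    return CohortAnalysis(manifest, measures, group_stats, severity_stats,
                          permutation, clusters, common, grid)


def _crop_to_mask(maps: np.ndarray, mask: np.ndarray, grid: Grid, margin: int = 2):
    """Crop subject maps and mask to the mask's bounding box (+margin)."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, np.array(grid.shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    cgrid = Grid(tuple(int(b - a) for a, b in zip(lo, hi)), grid.voxel_size,
                 tuple(grid.world(lo)))
    return maps[(slice(None),) + sl], mask[sl], cgrid, sl


def _embed_result(res: PermutationResult, grid: Grid, mask: np.ndarray,
                  bbox) -> PermutationResult:
    def emb(a, fill):
        out = np.full(grid.shape, fill, dtype=float)
        out[bbox] = a
        return out
    return PermutationResult(grid, mask, emb(res.t_map, 0.0), emb(res.tfce_map, 0.0),
                             emb(res.corrected_p, 1.0), res.n_perm, res.max_null,
                             res.warnings)
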