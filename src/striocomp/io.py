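"""NIfTI / table / run-log serialization.

All volumes are written in RAS axis order with an explicit diagonal affine;
tables are delimited text; every run directory gets a machine-readable run
log with parameters, seeds, package version and output checksums.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, _plain
from .grid import Grid
from .parcellation import CompartmentParcellation, ProbabilityMaps
from .phantom import ALL_REGIONS, PhantomSubject
from .somatotopy import SomatotopicZoneSet


def save_volume(data: np.ndarray, grid: Grid, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    img.header.set_zooms((grid.voxel_size,) * 3 + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine); volumes are reoriented to RAS on load."""
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    return np.asarray(img.dataobj), img.affine


def load_probability_maps(p_matrix_path: str | Path, p_striosome_path: str | Path,
                          striatal_mask_path: str | Path,
                          min_total_count: int = 10) -> ProbabilityMaps:
    """Build :class:`ProbabilityMaps` from externally supplied NIfTI maps."""
    pm, aff = load_volume(p_matrix_path)
    ps, _ = load_volume(p_striosome_path)
    mask, _ = load_volume(striatal_mask_path)
    mask = mask > 0.5
    grid = Grid(pm.shape, float(aff[0, 0]), tuple(aff[:3, 3]))
    seeded = mask & ((pm + ps) > 0.5)
    return ProbabilityMaps(grid, pm.astype(float), ps.astype(float), seeded, mask,
                           min_total_count)


def write_phantom_subject(subject: PhantomSubject, out_dir: str | Path) -> list[Path]:
    """Write one subject's grids: nuclei, ground-truth compartments, the
    eigenvalue triples as a 4D volume, and an integer-labelled bait atlas
    with a legend table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = subject.grid
    sid = subject.subject_id
    paths = [
        save_volume(subject.nuclei, grid, out / f"{sid}_nuclei.nii"),
        save_volume(subject.gt_compartment, grid, out / f"{sid}_gt_compartment.nii"),
        save_volume(subject.rd_field, grid, out / f"{sid}_eigenvalues.nii"),
    ]
    atlas = np.zeros(grid.shape, dtype=np.float32)
    legend = []
    for i, name in enumerate(ALL_REGIONS, start=1):
        atlas[subject.bait_atlas.regions[name]] = i
        legend.append({"label": i, "region": name,
                       "affinity": subject.bait_atlas.affinity[name]})
    paths.append(save_volume(atlas, grid, out / f"{sid}_bait_atlas.nii"))
    legend_path = out / f"{sid}_bait_legend.tsv"
    pd.DataFrame(legend).to_csv(legend_path, sep="\t", index=False)
    paths.append(legend_path)
    return paths


def write_streamline_counts(counts, grid: Grid, out_dir: str | Path,
                            prefix: str) -> list[Path]:
    """Serialize classification-targets counts: a 4D volume (one 3D volume
    per target) plus a per-target summary table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grids = counts.count_grid(grid.shape)
    stacked = np.stack([grids[name] for name in counts.target_names], axis=-1)
    paths = [save_volume(stacked, grid, out / f"{prefix}_counts.nii")]
    summary = pd.DataFrame({
        "target": list(counts.target_names),
        "total_count": [int(grids[n].sum()) for n in counts.target_names],
        "normalized_per_mm3": [counts.normalized_totals()[n]
                               for n in counts.target_names],
        "launched_per_voxel": counts.launched,
    })
    paths.append(write_table(summary, out / f"{prefix}_counts.tsv"))
    return paths


def write_parcellation(prob: ProbabilityMaps, parc: CompartmentParcellation,
                       out_dir: str | Path, prefix: str) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return [
        save_volume(prob.p_matrix, prob.grid, out / f"{prefix}_p_matrix.nii"),
        save_volume(prob.p_striosome, prob.grid, out / f"{prefix}_p_striosome.nii"),
        save_volume(prob.seeded_mask.astype(np.float32), prob.grid,
                    out / f"{prefix}_seeded.nii"),
        save_volume(parc.labels, parc.grid, out / f"{prefix}_labels.nii"),
    ]


def write_zones(zone_set: SomatotopicZoneSet, grid: Grid, out_dir: str | Path,
                prefix: str) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol = np.zeros(grid.shape, dtype=np.float32)
    legend = []
    for i, (name, mask) in enumerate(zone_set.zones.items(), start=1):
        vol[mask] = i
        legend.append({"label": i, "zone": name, "n_voxels": int(mask.sum())})
    paths = [save_volume(vol, grid, out / f"{prefix}_zones.nii")]
    legend_path = out / f"{prefix}_zone_legend.tsv"
    pd.DataFrame(legend).to_csv(legend_path, sep="\t", index=False)
    paths.append(legend_path)
    return paths


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_log(out_dir: str | Path, config: RunConfig, stage: str,
                  outputs: list[Path], extra: dict | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {
        "package": "striocomp",
        "version": __version__,
        "stage": stage,
        "seed": config.seed,
        "config": _plain(config.to_dict()),
        "outputs": {str(p): sha256(p) for p in outputs},
    }
    if extra:
        log.update(extra)
    path = out / f"runlog_{stage}.json"
    path.write_text(json.dumps(log, indent=2, default=str))
    return path
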