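"""Run configuration: one dataclass tree, YAML round-trip, seed handling.

A single global seed deterministically spawns per-stage sub-seeds, so every
stage is reproducible on its own and no two stages share a stream.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .inference import TFCEParams
from .phantom import CohortSpec, PhantomParams
from .tracking import TrackingParams


@dataclass
class ParcellationConfig:
    bias_threshold: float = 0.55
    min_total_count: int = 10
    high_bias_fraction: float = 0.13
    cluster_connectivity: int = 26


@dataclass
class ZoneConfig:
    floor_percentile: float = 75.0
    size_bound: float = 4.0


@dataclass
class InferenceConfig:
    n_perm: int = 1000
    variance_smoothing_mm: float = 2.0
    alpha: float = 0.05
    tfce: TFCEParams = field(default_factory=TFCEParams)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run byte-for-byte."""

    seed: int = 0
    output_dir: str = "striocomp_out"
    phantom: PhantomParams = field(default_factory=PhantomParams)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    parcellation: ParcellationConfig = field(default_factory=ParcellationConfig)
    zones: ZoneConfig = field(default_factory=ZoneConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the global seed."""
        digest = sum((i + 1) * b for i, b in enumerate(stage.encode()))
        return int(np.random.SeedSequence([self.seed, digest]).generate_state(1)[0]
                   % (2**31 - 1))

    def resolved(self) -> "RunConfig":
        """Copy with stage seeds injected into the stage configs."""
        return dataclasses.replace(
            self,
            cohort=dataclasses.replace(self.cohort, rng_seed=self.stage_seed("cohort"),
                                       phantom=self.phantom),
            tracking=dataclasses.replace(self.tracking, rng_seed=self.stage_seed("tracking")),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            v = data[f.name]
            if f.name == "phantom":
                v = _load(PhantomParams, v)
            elif f.name == "cohort":
                v = dict(v)
                v["phantom"] = _load(PhantomParams, v.get("phantom", {}))
                v = CohortSpec(**v)
            elif f.name == "tracking":
                v = _load(TrackingParams, v)
            elif f.name == "parcellation":
                v = _load(ParcellationConfig, v)
            elif f.name == "zones":
                v = _load(ZoneConfig, v)
            elif f.name == "inference":
                v = dict(v)
                v["tfce"] = _load(TFCEParams, v.get("tfce", {}))
                v = InferenceConfig(**v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        missing = [k for k in ("seed", "output_dir") if k not in data]
        if missing:
            raise ValueError(f"config is missing required field(s): {missing}")
        return cls.from_dict(data)


def _load(cls, data):
    if isinstance(data, cls):
        return data
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} field(s): {sorted(unknown)}")
    kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()}
    return cls(**kwargs)


def _plain(obj):
    """YAML-safe plain types (tuples -> lists)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
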