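"""Run configuration shared across pipeline stages.

All tunable thresholds of the pipeline live in a single :class:`PipelineConfig`
so that a full run is reproducible from one YAML file plus one seed. Every
randomized stage derives its generator from ``seed`` plus a fixed per-stage
offset (see the stage modules), so re-running with the same config is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "STAGE_SEED_OFFSETS"]

# Fixed offsets added to PipelineConfig.seed when a stage needs its own stream.
STAGE_SEED_OFFSETS = {
    "simulate": 101,
    "lochness_null": 211,
    "power": 307,
    "screen": 401,
}


@dataclass
class PipelineConfig:
    """Thresholds and sizes used throughout the pipeline.

    Defaults follow the whole-embryo QC and testing conventions: cells with
    UMI <= 250 or detected genes <= 100 are discarded; mitochondrial fraction
    above 10% or ribosomal fraction above 5% marks low-quality cells; doublet
    scores above 0.2 flag cells and subclusters with more than 15% flagged
    cells are dropped wholesale; composition tests are reported at an
    uncorrected 5% level after removing cell types with a mean of fewer than
    10 cells per embryo; log2 composition ratios are clipped at +/-2 for
    display.
    """

    seed: int = 0
    umi_min: int = 250
    gene_min: int = 100
    mt_max: float = 0.10
    ribo_max: float = 0.05
    doublet_score_max: float = 0.2
    doublet_subcluster_frac: float = 0.15
    knn_annotation_k: int = 15
    alpha: float = 0.05
    n_permutations: int = 100
    n_power_sims: int = 100
    power_threshold: float = 0.8
    timescore_k: int = 10
    log2_display_clip: float = 2.0
    min_mean_cells: float = 10.0

    def __post_init__(self) -> None:
        for name in ("mt_max", "ribo_max", "doublet_subcluster_frac", "alpha",
                     "power_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v!r}")
        for name in ("umi_min", "gene_min", "knn_annotation_k",
                     "n_permutations", "n_power_sims", "timescore_k"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a count >= 1, got {v!r}")
            setattr(self, name, int(v))
        if self.log2_display_clip <= 0:
            raise ValueError("log2_display_clip must be positive")
        if self.min_mean_cells < 0:
            raise ValueError("min_mean_cells must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
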