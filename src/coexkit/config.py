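"""Pipeline configuration: one YAML file, every stage threshold in one place."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All stage thresholds, input paths and run settings.

    Defaults follow the conventional blood-transcriptome analysis: DEG
    selection at FC > 1.2 and P < 0.05; enrichment reported at P < 0.05
    with GO-Tree terms at P < 0.01; hard correlation threshold 0.8;
    differential-coreness threshold 30; module cutting with deep split 2,
    cut height 0.99 and minimum size 30; hub calling at MM > 0.9; core TFs
    at more than 10 targets.
    """

    # inputs
    expression: str = ""
    groups: str = ""
    gene_sets: str = ""
    go_dag: str = ""
    tf_targets: str = ""
    pathway_links: str | None = None
    outdir: str = "results"
    case_label: str | None = None

    # dge
    p_thr: float = 0.05
    fc_thr: float = 1.2

    # enrichment
    enrich_p: float = 0.05
    gotree_p: float = 0.01
    pathway_p: float = 0.05

    # netcore
    r_thr: float = 0.8
    coexp_p: float = 0.05
    dif_kcore_thr: int = 30

    # wgcna
    beta_candidates: list[int] = field(default_factory=lambda: list(range(1, 21)))
    target_r2: float = 0.8
    cut_height: float = 0.99
    min_module_size: int = 30
    deep_split: int = 2
    mm_thr: float = 0.9

    # trn
    min_targets: int = 10
    focal_tf: str | None = None

    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.p_thr < 1:
            raise ValueError(f"p_thr must lie in (0, 1), got {self.p_thr}")
        if self.fc_thr <= 1:
            raise ValueError(f"fc_thr must exceed 1, got {self.fc_thr}")
        for name in ("enrich_p", "gotree_p", "pathway_p", "coexp_p"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if not 0 < self.r_thr <= 1:
            raise ValueError(f"r_thr must lie in (0, 1], got {self.r_thr}")
        if self.dif_kcore_thr < 0:
            raise ValueError("dif_kcore_thr must be non-negative")
        if not self.beta_candidates or min(self.beta_candidates) <= 0:
            raise ValueError("beta_candidates must be positive")
        if not 0 <= self.cut_height <= 1:
            raise ValueError("cut_height must lie in [0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must lie in 0..4")
        if self.min_targets < 0:
            raise ValueError("min_targets must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        config.validate()
        return config

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
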