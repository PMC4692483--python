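"""Pipeline configuration: a flat YAML file plus programmatic overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .clusters import ClusterConfig


@dataclass
class PipelineConfig:
    """Everything a full run needs; thresholds default to the standard cascade."""

    # inputs
    genome: str | None = None
    matrix: str | None = None
    matrix_format: str = "counts"
    refflat: str | None = None
    exons_bed: str | None = None
    repeats_bed: str | None = None
    ctcf_bed: str | None = None
    lifted_bed: str | None = None
    out_dir: str = "glicluster_run"
    # scan parameters
    min_mss: float = 0.75
    concordance_positions: tuple[int, int] = (4, 6)
    civ_core_min: float = 70.0
    softmask_as_repeat: bool = False
    # background parameters
    background_model: str = "flip_gc_at"
    n_raw: int = 1000
    n_replicates: int = 100
    seed: int = 0
    # cluster parameters
    cluster: ClusterConfig = field(default_factory=ClusterConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_mss <= 1.0):
            raise ValueError(f"min_mss must lie in [0, 1], got {self.min_mss}")
        if self.n_raw < 1 or self.n_replicates < 1:
            raise ValueError("n_raw and n_replicates must be positive")
        self.concordance_positions = tuple(self.concordance_positions)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cluster = ClusterConfig(**data.pop("cluster", {}))
        return cls(cluster=cluster, **data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["concordance_positions"] = list(self.concordance_positions)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
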