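"""Run configuration: every bin width, replicate count, level and seed
used by the pipeline, loadable from a YAML mapping with defaults for
anything omitted."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    data_dir: str | None = None
    output_dir: str = "results"
    acf_bin_s: float = 1.0
    acf_max_lag_s: float = 60.0
    display_bin_s: float = 10.0
    consolidation_bin_min: float = 15.0
    n_replicates: int = 10000
    alpha: float = 0.05
    q_threshold: float = 0.05
    bonferroni_comparisons: int = 2  # contrasts per figure-level analysis
    block_length_s: float | None = None  # None -> estimated from the acf
    default_block_s: float = 10.0
    ri_convention: str = "text"  # or "printed"
    min_state_dwell_s: float = 60.0
    cluster_null_scheme: str = "permute_within"
    seed: int = 0
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.q_threshold < 1.0:
            raise ValueError("alpha and q must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.ri_convention not in ("text", "printed"):
            raise ValueError("ri_convention must be 'text' or 'printed'")
        for name in ("acf_bin_s", "display_bin_s", "consolidation_bin_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
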