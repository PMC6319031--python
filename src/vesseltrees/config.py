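"""Pipeline configuration: every stage default in one overridable block."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # filterbank
    dictionary_entries: list | None = None   # [(sigma3, c3), ...]; None = default
    support_radius: int = 5
    sigma_delta: float = 0.8
    sigma_nu: float = 8.0
    # pyramid and seeding
    scales: list = field(default_factory=lambda: [0.25, 0.5, 1.0])
    icosphere_level: int = 2
    quantile_p: float = 75.0
    hessian_sigma: float = 1.0
    theta_max_bases: int = 2000
    alpha: list | None = None
    # connectivity
    mode: str = "auto"                       # auto | seeded
    mu: float = 3.0
    speed_gamma: float = 0.7
    propagation_radius: float = 30.0         # mm; seeded mode uses infinity
    edges_per_node: int = 10
    max_sources: int = 200
    refine_max_iter: int = 10
    # tree
    leaf_prune_mm: float = 5.0
    geodesic_threshold: float = float("inf")
    roi_mask_paths: list = field(default_factory=list)
    # misc
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.quantile_p <= 100:
            raise ValueError("quantile_p must be in (0, 100]")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if any(not 0 < s <= 1 for s in self.scales):
            raise ValueError("scales must be in (0, 1]")
        if self.mode not in ("auto", "seeded"):
            raise ValueError("mode must be 'auto' or 'seeded'")
        self.scales = sorted(self.scales)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))
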