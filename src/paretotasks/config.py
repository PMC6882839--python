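"""Run configuration: one flat document controlling every stage.

All stochastic stages consume seeds derived deterministically from
``seed``, so a config plus seed reproduces a run bit-for-bit. Defaults
follow the study conventions: 1000 t-ratio shuffles, 1e5 alignment
shuffles, significance at p < 0.01, FDR at 10%, a first distance bin of
max(50, 5% of samples), four drug bins, five heterogeneity PCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    k_range: list[int] = field(default_factory=lambda: [3, 4, 5])
    n_shuffles_tratio: int = 1000
    n_shuffles_alignment: int = 100_000
    significance_alpha: float = 0.01
    fdr_q: float = 0.10
    bin_base_count: int = 50
    bin_min_fraction: float = 0.05
    n_peak_bins: int = 5
    n_drug_bins: int = 4
    min_lines_per_bin: int = 5
    n_pcs_alignment: int = 10
    n_pcs_heterogeneity: int = 5
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        for name in ("n_shuffles_tratio", "n_shuffles_alignment", "bin_base_count",
                     "n_peak_bins", "n_drug_bins", "min_lines_per_bin",
                     "n_pcs_alignment", "n_pcs_heterogeneity"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("significance_alpha", "fdr_q", "bin_min_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not self.k_range or any(k < 3 for k in self.k_range):
            raise ValueError("k_range values must be >= 3")
        if sorted(self.k_range) != list(self.k_range):
            raise ValueError("k_range must be ascending")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        stages = ("simulate", "fit", "enrich", "universal", "mutations", "drugs", "cells")
        if stage not in stages:
            raise ValueError(f"unknown stage {stage!r}")
        return (self.seed * len(stages) + stages.index(stage)) % (2**31)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
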