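"""Pipeline configuration.

All tunable thresholds in one place, with the defaults the analysis is
defined by: DEG selection at fold change 1.5 / p 0.05 at >= 2 time
points, synergy edges at Pearson r > 0.7 with >= 3 shared targets,
100 degree-preserving null networks, enrichment significance at >= 10
members and p < 0.001. Values can be overridden by a TOML file and by
CLI flags, with precedence CLI > file > defaults.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    # DEG selection
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    min_timepoints: int = 2
    # preprocessing
    loess_span: float = 0.3
    n_harmonics: int = 4
    # NCA solver
    nca_tol: float = 1e-6
    nca_max_iter: int = 500
    nca_restarts: int = 5
    # synergy network
    pcc_threshold: float = 0.7
    min_shared: int = 3
    # randomization
    n_random: int = 100
    # enrichment
    min_overlap: int = 10
    alpha: float = 0.001
    # root seed; all stage seeds are split from it deterministically
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "p_threshold", "loess_span", "nca_tol",
                     "pcc_threshold", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_threshold", "alpha", "loess_span"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_toml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
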