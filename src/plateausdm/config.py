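"""Run configuration shared by all pipeline stages."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, fields


@dataclass
class RunConfig:
    """Flat key-value configuration mirrored one-to-one by the JSON config file.

    Defaults encode the modelling protocol: 1-km nominal cells, spatial
    thinning on a 10-km grid, collinearity cutoff |r| = 0.7, 10,000 background
    cells, 15 replicates with a 25% random test split, regularization
    multiplier 1, and the logistic prevalence constant tau = 0.5.
    """

    cell_size_km: float = 1.0
    thinning_cell_km: float = 10.0
    correlation_cutoff: float = 0.7
    background_n: int = 10000
    replicates: int = 15
    test_fraction: float = 0.25
    regularization_multiplier: float = 1.0
    tau: float = 0.5
    random_seed: int = 0
    convergence_tol: float = 1e-5
    max_iterations: int = 500

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        if not (0 < self.correlation_cutoff <= 1):
            raise ValueError("correlation_cutoff must lie in (0, 1]")
        for name in ("background_n", "replicates", "max_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cell_size_km", "thinning_cell_km", "regularization_multiplier",
                     "convergence_tol", "cell_size_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.tau < 1):
            raise ValueError("tau must lie in (0, 1)")

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})
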