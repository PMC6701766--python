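"""Pipeline configuration: a validated, serialisable description of one run.

A run is fully reproducible from its config and seed; every output table
carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .synthetic import REFERENCE


@dataclass
class PipelineConfig:
    seed: int = 0
    # synthetic catchment
    shape: tuple[int, int] = tuple(REFERENCE["shape"])
    cell_size_cm: float = REFERENCE["cell_size_cm"]
    n_plots: int = REFERENCE["n_plots"]
    n_bd: int = REFERENCE["n_bd"]
    soc_noise_sd: float = REFERENCE["soc_noise_sd"]
    bd_noise_sd: float = REFERENCE["bd_noise_sd"]
    # terrain
    radii: tuple[int, ...] = (1, 2, 4, 6, 8)
    # learning
    learners: tuple[str, ...] = ("rf",)
    cv_folds: int = 10
    # depth functions / voxel grid
    soc_families: tuple[str, ...] = ("exp", "poly3")
    bd_family: str = "log"
    depth_from_cm: float = 0.0
    depth_to_cm: float = 50.0
    step_cm: float = 5.0
    soc_clamp_floor: float = 0.0
    # stock aggregation bounds (always explicit)
    stock_ranges_cm: tuple[tuple[float, float], ...] = ((0.0, 20.0), (20.0, 40.0), (0.0, 40.0))

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_bd > self.n_plots:
            raise ValueError("n_bd cannot exceed n_plots")
        for fam in (*self.soc_families, self.bd_family):
            if fam not in ("poly3", "poly2", "log", "exp"):
                raise ValueError(f"unknown depth-function family {fam!r}")
        for kind in self.learners:
            if kind not in ("rf", "svm_rbf", "mars_like"):
                raise ValueError(f"unknown learner {kind!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        fixed = dict(raw)
        for key in ("shape", "radii", "learners", "soc_families"):
            if key in fixed and isinstance(fixed[key], list):
                fixed[key] = tuple(fixed[key])
        if "stock_ranges_cm" in fixed:
            fixed["stock_ranges_cm"] = tuple(tuple(r) for r in fixed["stock_ranges_cm"])
        return cls(**fixed)
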