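"""Pipeline configuration and output provenance helpers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml

from . import __version__

__all__ = ["PipelineConfig", "config_hash", "provenance_header"]


@dataclass
class PipelineConfig:
    """Everything the end-to-end analysis needs beyond the input tables."""

    covariate_set: str = "set2"
    grid_step_days: float = 30.0
    slice_days: float = 30.0
    horizon_age: float = 110.0
    n_individuals: int = 8600
    bootstrap_reps: int = 300
    bootstrap_method: str = "normal"
    weights_window: tuple[float, float] = (45.0, 55.0)
    life_table_a: float = 0.5
    min_person_years: float = 10.0
    seed: int = 0
    integration_rule: str = "trapezoid"

    def validate(self) -> None:
        if self.horizon_age <= 50:
            raise ValueError("horizon_age must exceed 50")
        if self.covariate_set not in ("set1", "set2", "set3"):
            raise ValueError(f"unknown covariate set {self.covariate_set!r}")
        if self.grid_step_days <= 0 or self.slice_days <= 0:
            raise ValueError("grid_step_days and slice_days must be positive")
        if self.bootstrap_reps < 0 or self.n_individuals <= 0:
            raise ValueError("bootstrap_reps must be >= 0 and n_individuals > 0")
        lo, hi = self.weights_window
        if not lo < hi:
            raise ValueError("weights_window must be a nonempty interval")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "weights_window" in known:
            known["weights_window"] = tuple(known["weights_window"])
        cfg = cls(**known)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weights_window"] = list(d["weights_window"])
        return d


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(cfg: PipelineConfig) -> str:
    """Comment header stamped on every output file."""
    return (f"# statelife {__version__} | config {config_hash(cfg)} "
            f"| seed {cfg.seed}\n")
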