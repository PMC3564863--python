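"""Declarative run configuration for the end-to-end pipeline.

One YAML file describes a full simulated experiment: generator settings,
detector thresholds, HMM options, the protein-calling protocol, and the
master seed.  Every stochastic stage consumes a child seed spawned from the
master seed, so a config reproduces all numeric outputs bit-for-bit on one
platform.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .signals import DT_S
from .synthetic import SyntheticConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 7
    dt_s: float = DT_S
    # trace stage (capture-rate statistics)
    voltages_mV: list = field(default_factory=lambda: [160.0, 180.0, 200.0, 220.0, 240.0])
    trace_duration_s: float = 20.0
    trace_class: str = "wt"
    # event pools (training / calling / kinetics)
    pool_size: int = 1200
    pool_voltage_mV: float = 200.0
    # detector
    enter_frac: float = 0.8
    exit_frac: float = 0.9
    # HMM
    K: int = 3
    tol: float = 1e-6
    max_iter: int = 100
    # protocol
    case: int = 1
    n_per_class: int = 400
    n_per_class_case2: int = 30
    n_boot: int = 200
    # kinetics
    kinetics_events: int = 400
    synthetic_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.seed is None:
            raise ValueError("a seed must be set")
        if self.case not in (1, 2):
            raise ValueError("case must be 1 or 2")

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(dt_s=self.dt_s, rng_seed=self.seed,
                               **self.synthetic_overrides)

    def child_seeds(self, n: int) -> list[np.random.Generator]:
        return [np.random.default_rng(s)
                for s in np.random.SeedSequence(self.seed).spawn(n)]

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ValueError(f"invalid config key: {exc}") from exc
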