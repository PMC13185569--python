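"""Model and run configuration.

All tunable constants of the dynamical model live in :class:`ModelConfig`;
pipeline-level settings (seeds, paths, thresholds) in :class:`RunConfig`.
Both serialize to plain dicts so a run can be reproduced from its YAML/JSON
config and a master seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ModelConfig", "RunConfig", "config_hash", "derive_seed"]


@dataclass(frozen=True)
class ModelConfig:
    """Constants of the clamped generalized Lotka-Volterra model.

    The per-capita growth rate of species ``i`` is
    ``g_i * max(growth_floor, 1 + sum_j a_ij X_j)`` and its effective
    carrying capacity is ``1 + sum_j b_ij X_j`` clamped into
    ``[capacity_floor, capacity_cap]``. Densities are normalized by each
    species' own monoculture capacity, so the monoculture equilibrium is 1.

    Parameters
    ----------
    growth_floor:
        Lower clamp on the growth-modulation factor (default ``1e-3``),
        keeping the per-capita growth rate sign-definite.
    capacity_floor, capacity_cap:
        Clamp bounds on the effective capacity (defaults ``1e-20`` and
        ``2``); the floor makes strongly inhibited species collapse instead
        of producing a negative capacity, the cap limits mutualistic runaway.
    rel_tol, abs_tol:
        Solver tolerances. The ``1e-20`` floor makes the system extremely
        stiff when a capacity collapses, hence tight defaults and a
        stiff-capable solver.
    horizon_h:
        Invasion / stability simulation horizon in hours (default 48).
    experiment_horizon_h:
        Co-culture experiment horizon in hours (default 24).
    equilibration_h:
        Long horizon used when an equilibrium must be found by integration.
    extinction_floor:
        Normalized density below which a species is set to exactly 0 at the
        end of a trajectory.
    inoculum_od:
        Experimental inoculum in OD units (default 0.05).
    """

    growth_floor: float = 1e-3
    capacity_floor: float = 1e-20
    capacity_cap: float = 2.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    horizon_h: float = 48.0
    experiment_horizon_h: float = 24.0
    equilibration_h: float = 500.0
    extinction_floor: float = 1e-12
    inoculum_od: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.capacity_floor < 1.0 < self.capacity_cap):
            raise ValueError(
                "require 0 < capacity_floor < 1 < capacity_cap, got "
                f"{self.capacity_floor!r}, {self.capacity_cap!r}"
            )
        if self.growth_floor <= 0:
            raise ValueError("growth_floor must be > 0")
        for name in ("rel_tol", "abs_tol", "horizon_h", "experiment_horizon_h",
                     "equilibration_h", "inoculum_od"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        return cls(**d)


@dataclass
class RunConfig:
    """Pipeline configuration: model constants, seeds, paths and thresholds."""

    model: ModelConfig = field(default_factory=ModelConfig)
    master_seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    growth_call_fold: float = 2.0          # growth iff final OD >= fold * inoculum
    experimental_threshold: float = 0.05   # invader fraction at 24 h
    fit_window: int = 5                    # rolling-regression window (points)
    od_floor: float = 1e-3                 # OD detection limit before log
    n_sensitivity_draws: int = 100
    n_ensemble_invaders: int = 100

    def __post_init__(self) -> None:
        if isinstance(self.model, dict):
            self.model = ModelConfig.from_dict(self.model)
        if not 0.0 < self.experimental_threshold < 1.0:
            raise ValueError("experimental_threshold must be in (0, 1)")
        if self.growth_call_fold <= 1.0:
            raise ValueError("growth_call_fold must be > 1")
        if self.fit_window < 3:
            raise ValueError("fit_window must be >= 3")
        if self.n_sensitivity_draws < 2:
            raise ValueError("n_sensitivity_draws must be >= 2")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Load a YAML (or JSON, a YAML subset) config file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(data)
        for key, p in cfg.paths.items():
            if key.startswith("in_") and not Path(p).exists():
                raise FileNotFoundError(f"input path {key}={p!r} does not exist")
        return cfg

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return derive_seed(self.master_seed, stage)


def derive_seed(master: int, label: str) -> int:
    """Derive a child seed < 2**31 from a master seed and a stage label."""
    h = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def config_hash(cfg: RunConfig | ModelConfig) -> str:
    """Hash of the semantic config content (stable across key order)."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
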