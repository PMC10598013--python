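"""Run configuration: schema validation, defaults, reproducibility plumbing.

A run is fully described by one YAML (or JSON) document; unknown keys are
rejected so a typo cannot silently fall back to a default.  Every run
writes its fully-resolved configuration next to its outputs, and all
randomness (graph wiring, randomised initial conditions) flows from the
single ``seed`` field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = ["RunConfig", "SolverConfig", "NetworkConfig", "AnalysisConfig",
           "load_config", "dump_config", "write_outputs"]


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_steps: int = 2000
    step: float = 1.0
    memory: Optional[int] = None       # None: full memory

    @model_validator(mode="after")
    def _check(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.memory is not None and self.memory <= 0:
            raise ValueError("memory must be positive or null")
        return self


class NetworkConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    N: int = 100
    mean_degree: float = 7.0
    coupling: float = 0.0
    r: int = 65
    s: int = 35
    theta: float = 1.0
    phi: float = 0.8

    @model_validator(mode="after")
    def _check(self):
        if self.r + self.s != self.N:
            raise ValueError(f"order partition r + s = {self.r + self.s} != N = {self.N}")
        return self


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    quiescence_amplitude: float = 1.0
    burst_gap_factor: float = 3.0
    mmo_peak_ratio: float = 0.4
    transient_fraction: float = 0.5
    refractory: int = 3


class RunConfig(BaseModel):
    """Top-level, schema-validated description of one run."""

    model_config = ConfigDict(extra="forbid")

    model: Literal["2d", "3d", "network", "reduced"] = "2d"
    group: str = "i"
    orders: List[float] = [1.0]
    current: Optional[float] = None     # applied current; None: group default
    initial_state: Optional[List[float]] = None
    seed: int = 0
    solver: SolverConfig = SolverConfig()
    network: NetworkConfig = NetworkConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    out_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self):
        for o in self.orders:
            if not (0.0 < o <= 1.0):
                raise ValueError(f"fractional order {o} outside (0, 1]")
        return self


def load_config(path=None, overrides: Optional[dict] = None) -> RunConfig:
    """Load and validate a config file; flag overrides win over file values."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root of {path} must be a mapping")
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if "." in key:
            section, sub = key.split(".", 1)
            data.setdefault(section, {})[sub] = value
        else:
            data[key] = value
    return RunConfig(**data)


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(json.loads(cfg.model_dump_json()), sort_keys=True)


def write_outputs(results: dict, cfg: RunConfig, out_dir) -> list:
    """Write run artefacts; deterministic given identical inputs.

    ``results`` maps names to writable objects: Trajectory /
    NetworkTrajectory (CSV), NetworkSpec (edge list + JSON metadata), or
    plain JSON-serialisable dicts.  The resolved config is always written
    alongside.  Returns the list of written paths.
    """
    from .frac_calculus import Trajectory
    from .network import NetworkSpec, NetworkTrajectory

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    cfg_path = out / "config.yaml"
    cfg_path.write_text(dump_config(cfg))
    written.append(cfg_path)

    for name, obj in results.items():
        if isinstance(obj, Trajectory):
            p = out / f"{name}.csv"
            obj.write_csv(p)
        elif isinstance(obj, NetworkTrajectory):
            p = out / f"{name}.csv"
            obj.to_frame().to_csv(p, index=False)
        elif isinstance(obj, NetworkSpec):
            p = out / f"{name}.edges"
            obj.write_edge_list(p)
            meta = out / f"{name}.json"
            meta.write_text(
                json.dumps(
                    {
                        "N": obj.N,
                        "target_mean_degree": obj.target_mean_degree,
                        "seed": obj.seed,
                        "coupling": obj.coupling,
                        "rewired_nodes": list(obj.rewired_nodes),
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            written.append(meta)
        else:
            p = out / f"{name}.json"
            p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
        written.append(p)
    return written
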