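"""Run configuration and manifests.

Configs are YAML with fixed units (mm, MPa, N, degrees, days, years).
Validation reports the dotted field path of the first violation. Every run
writes a :class:`RunManifest` recording the config snapshot, seeds, package
version, per-stage wall times and the output file registry, so a run can be
reproduced exactly from its manifest at the same code version.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from . import __version__
from .cohort import OutcomeModelConfig
from .deployment import DeploymentConfig
from .errors import ConfigError
from .io import root_params_from_dict, root_params_to_dict, write_json
from .anatomy import RootParams


def _require(cond: bool, path: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{path}: {message}")


def _check_type(value, types, path: str):
    _require(isinstance(value, types), path,
             f"expected {getattr(types, '__name__', types)}, got {type(value).__name__}")
    return value


@dataclass
class SimulationConfig:
    """One-patient run: anatomy, device choice, deployment, seed."""

    root: RootParams
    device: str = "EvolutPRO-29"
    deployment: DeploymentConfig = field(default_factory=DeploymentConfig)
    mesh_n_circ: int = 72
    mesh_dz: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        _check_type(raw, dict, "<root>")
        try:
            root = root_params_from_dict(_check_type(raw.get("root", {}) or {}, dict, "root"))
            root.validate()
        except ConfigError:
            raise
        except Exception as exc:
            raise ConfigError(f"root: {exc}") from exc
        dep_raw = _check_type(raw.get("deployment", {}) or {}, dict, "deployment")
        known = {f.name for f in dataclasses.fields(DeploymentConfig)}
        for key in dep_raw:
            _require(key in known, f"deployment.{key}", "unknown field")
        try:
            dep = DeploymentConfig(**dep_raw)
        except Exception as exc:
            raise ConfigError(f"deployment: {exc}") from exc
        mesh = _check_type(raw.get("mesh", {}) or {}, dict, "mesh")
        n_circ = int(mesh.get("n_circ", 72))
        dz = float(mesh.get("dz", 0.5))
        _require(n_circ >= 16, "mesh.n_circ", "must be >= 16")
        _require(dz > 0, "mesh.dz", "must be > 0")
        device = str(raw.get("device", "EvolutPRO-29"))
        seed = int(raw.get("seed", 0))
        return cls(root=root, device=device, deployment=dep,
                   mesh_n_circ=n_circ, mesh_dz=dz, seed=seed)

    def to_dict(self) -> dict:
        return {
            "root": root_params_to_dict(self.root),
            "device": self.device,
            "deployment": dataclasses.asdict(self.deployment),
            "mesh": {"n_circ": self.mesh_n_circ, "dz": self.mesh_dz},
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


@dataclass
class CohortConfig:
    """Cohort run: generation mode, size, outcome structure, seed."""

    n: int = 80
    mode: str = "statistical"
    outcome: OutcomeModelConfig = field(default_factory=OutcomeModelConfig)
    seed: int = 0
    mesh_n_circ: int = 48
    mesh_dz: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        _check_type(raw, dict, "<root>")
        n = int(raw.get("n", 80))
        _require(n >= 1, "n", "must be >= 1")
        mode = str(raw.get("mode", "statistical"))
        _require(mode in ("statistical", "physics"), "mode",
                 "must be 'statistical' or 'physics'")
        out_raw = _check_type(raw.get("outcome", {}) or {}, dict, "outcome")
        known = {f.name for f in dataclasses.fields(OutcomeModelConfig)}
        for key in out_raw:
            _require(key in known, f"outcome.{key}", "unknown field")
        for key in ("cpi_mcd", "cpi_no_mcd", "cpmax_mcd", "cpmax_no_mcd",
                    "lvef_baseline", "physics_coefficients"):
            if key in out_raw:
                out_raw[key] = tuple(out_raw[key])
        try:
            outcome = OutcomeModelConfig(mode=mode, **{k: v for k, v in out_raw.items()
                                                       if k != "mode"})
            outcome.validate()
        except ConfigError:
            raise
        except Exception as exc:
            raise ConfigError(f"outcome: {exc}") from exc
        mesh = _check_type(raw.get("mesh", {}) or {}, dict, "mesh")
        return cls(
            n=n, mode=mode, outcome=outcome, seed=int(raw.get("seed", 0)),
            mesh_n_circ=int(mesh.get("n_circ", 48)),
            mesh_dz=float(mesh.get("dz", 1.0)),
        )


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output set."""

    command: str
    config_snapshot: Dict[str, Any]
    seeds: Dict[str, int]
    version: str = __version__
    stage_wall_times: Dict[str, float] = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)
    _t0: Dict[str, float] = field(default_factory=dict, repr=False)

    def start(self, stage: str) -> None:
        self._t0[stage] = time.perf_counter()

    def stop(self, stage: str) -> None:
        self.stage_wall_times[stage] = time.perf_counter() - self._t0.pop(stage)

    def register(self, path) -> str:
        self.outputs.append(str(path))
        return str(path)

    def write(self, path) -> None:
        d = {
            "command": self.command,
            "version": self.version,
            "seeds": self.seeds,
            "config": self.config_snapshot,
            "stage_wall_times_s": self.stage_wall_times,
            "outputs": self.outputs,
        }
        write_json(d, path)
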