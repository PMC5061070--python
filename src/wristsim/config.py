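"""Configuration files, persistence and run manifests.

Config files are YAML or JSON with sections ``plant``, ``muscles``,
``controllers`` (one block per strategy), ``trajectory`` and
``experiment``, mirroring the corresponding dataclasses field for field;
unknown keys are rejected with the offending path. Units in all files:
angles deg, forces N, torques N m, moment arms and displacements mm.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .control import ControllerConfig, PIDGains
from .muscles import MuscleSet, default_muscles, load_muscle_table
from .plant import PlantConfig
from .protocols import ExperimentSpec, SimulationResult
from .trajectories import TrajectorySpec


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}; "
                          f"allowed: {sorted(allowed)}")


def _dataclass_from(section: dict, cls, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(section, fields, where)
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _plant_from(section: dict) -> PlantConfig:
    section = dict(section)
    for key in ("joint_limits_fe", "joint_limits_rud"):
        if key in section:
            section[key] = tuple(section[key])
    return _dataclass_from(section, PlantConfig, "plant")


def _gains_from(section: dict, where: str) -> PIDGains:
    return _dataclass_from(dict(section), PIDGains, where)


def _controller_from(section: dict, strategy: str) -> ControllerConfig:
    section = dict(section)
    where = f"controllers.{strategy}"
    if "axis_gains" in section:
        ag = section["axis_gains"]
        if len(ag) != 2:
            raise ConfigError(f"{where}.axis_gains: need exactly 2 entries "
                              "(FE, RUD)")
        section["axis_gains"] = tuple(
            _gains_from(g, f"{where}.axis_gains[{j}]") for j, g in enumerate(ag))
    if "force_gains" in section:
        section["force_gains"] = _gains_from(section["force_gains"],
                                             f"{where}.force_gains")
    if "f_max" in section and section["f_max"] is not None:
        section["f_max"] = np.asarray(section["f_max"], float)
    section["strategy"] = strategy
    return _dataclass_from(section, ControllerConfig, where)


@dataclass
class LoadedConfig:
    plant: PlantConfig
    muscles: MuscleSet
    controllers: dict[str, ControllerConfig]
    trajectory: TrajectorySpec
    experiment: ExperimentSpec


def load_config(path: str | Path) -> LoadedConfig:
    """Load and validate a full configuration file.

    Every dataclass invariant is checked on construction; defaults are
    filled for missing fields; unknown keys are rejected with a
    field-level message. The ``muscles`` section is either the string
    ``"default"`` or a path (relative to the config file) to a muscle CSV.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"{path}: parse error: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, {"plant", "muscles", "controllers", "trajectory",
                      "experiment"}, str(path))

    plant = _plant_from(raw.get("plant", {}))
    msrc = raw.get("muscles", "default")
    if msrc == "default":
        muscles = default_muscles()
    else:
        mpath = (path.parent / msrc) if not Path(msrc).is_absolute() else Path(msrc)
        muscles = load_muscle_table(mpath)
    controllers = {}
    for strategy, section in raw.get("controllers", {}).items():
        cc = _controller_from(section or {}, strategy)
        try:
            cc.validate_against(muscles)
        except ValueError as exc:
            raise ConfigError(f"controllers.{strategy}: {exc}") from exc
        controllers[strategy] = cc
    trajectory = _dataclass_from(dict(raw.get("trajectory", {})),
                                 TrajectorySpec, "trajectory")
    experiment = _dataclass_from(dict(raw.get("experiment", {})),
                                 ExperimentSpec, "experiment")
    return LoadedConfig(plant=plant, muscles=muscles, controllers=controllers,
                        trajectory=trajectory, experiment=experiment)


def default_config_path() -> Path:
    """Path of the packaged default configuration (tuned fixture gains)."""
    return Path(resources.files("wristsim") / "data" / "default_config.yaml")


def load_default_config() -> LoadedConfig:
    return load_config(default_config_path())


# --------------------------------------------------------------- time series

_ANGLE_COLS = ["time", "theta_fe_d", "theta_rud_d", "theta_fe", "theta_rud"]


def write_timeseries(result: SimulationResult, path: str | Path) -> None:
    """Write a simulation time series as CSV (header row, '.' decimal,
    UTF-8). Columns: time, desired and actual angles (deg), per-muscle
    forces (N), desired forces, commands (mm) and modes."""
    names = result.muscle_names
    df = pd.DataFrame({
        "time": result.time,
        "theta_fe_d": result.desired[:, 0],
        "theta_rud_d": result.desired[:, 1],
        "theta_fe": result.actual[:, 0],
        "theta_rud": result.actual[:, 1],
    })
    for j, n in enumerate(names):
        df[f"F_{n}"] = result.forces[:, j]
    for j, n in enumerate(names):
        df[f"Fd_{n}"] = result.desired_forces[:, j]
    for j, n in enumerate(names):
        df[f"cmd_{n}"] = result.commands[:, j]
    for j, n in enumerate(names):
        df[f"mode_{n}"] = result.modes[:, j] if len(result.modes) else []
    df.to_csv(path, index=False, encoding="utf-8")


def read_timeseries(path: str | Path) -> SimulationResult:
    """Read a time series written by :func:`write_timeseries`. Round trip
    is lossless to ~1e-9 (pandas full-precision float repr)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except Exception as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    missing = [c for c in _ANGLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} (line 1)")
    names = tuple(c[2:] for c in df.columns if c.startswith("F_"))
    n = len(df)
    return SimulationResult(
        time=df["time"].to_numpy(),
        desired=df[["theta_fe_d", "theta_rud_d"]].to_numpy(),
        actual=df[["theta_fe", "theta_rud"]].to_numpy(),
        forces=df[[f"F_{m}" for m in names]].to_numpy() if n else np.empty((0, len(names))),
        desired_forces=df[[f"Fd_{m}" for m in names]].to_numpy() if n else np.empty((0, len(names))),
        commands=df[[f"cmd_{m}" for m in names]].to_numpy() if n else np.empty((0, len(names))),
        modes=df[[f"mode_{m}" for m in names]].to_numpy(dtype=object) if n else np.empty((0, len(names)), object),
        muscle_names=names, completed=True, seed=-1, strategy="",
        orientation="", motion="", loop_period=float(df["time"].diff().median()) if n > 1 else 0.0)


# ----------------------------------------------------------------- manifest

@dataclass
class RunManifest:
    """Snapshot of everything needed to reproduce a run bit-identically:
    the resolved configs, the seed, the software version and the outputs."""

    seed: int
    config: dict
    outputs: list[str]
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc).isoformat())

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=_json_default))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def snapshot_config(plant: PlantConfig, controllers: dict[str, ControllerConfig],
                    trajectory: TrajectorySpec | None = None,
                    experiment: ExperimentSpec | None = None) -> dict:
    snap: dict = {"plant": dataclasses.asdict(plant),
                  "controllers": {k: dataclasses.asdict(v)
                                  for k, v in controllers.items()}}
    if trajectory is not None:
        snap["trajectory"] = dataclasses.asdict(trajectory)
    if experiment is not None:
        snap["experiment"] = dataclasses.asdict(experiment)
    return snap
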