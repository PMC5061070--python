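"""Evaluation protocol: closed-loop runs, kinematic metrics, repeatability
and co-contraction sweeps.

The protocol mirrors the physical evaluation it virtualizes: planar
flexion-extension (FE-30) and radioulnar deviation (RUD-10) plus the
complex dart thrower's and circumduction motions, each run with the hand
vertically upward and downward, five times per condition. Strategies are
compared on mean kinematic error, the same error normalized by motion
amplitude, repeatability (SD of the mean error across repeats) and the
muscle-force distributions they produce.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .control import ControllerConfig, ForceProfile, make_controller
from .muscles import MuscleSet, default_muscles
from .plant import PlantConfig, WristPlant
from .trajectories import MotionSample, TrajectorySpec, make_trajectory


@dataclass
class ExperimentSpec:
    strategies: list[str] = field(default_factory=lambda: ["hybrid", "cascade"])
    orientations: list[str] = field(default_factory=lambda: ["downward", "upward"])
    motions: list[str] = field(default_factory=lambda: ["FE30", "RUD10"])
    repeats: int = 5
    seed: int = 0
    sweep: dict | None = None  # {"parameter": "f0"|"rho", "values": [...]}

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.strategies:
            raise ValueError("strategy list must not be empty")
        if self.sweep is not None:
            if self.sweep.get("parameter") not in ("f0", "rho"):
                raise ValueError("sweep parameter must be 'f0' or 'rho'")
            if not self.sweep.get("values"):
                raise ValueError("sweep values must not be empty")


@dataclass
class SimulationResult:
    """Uniformly sampled closed-loop time series plus a config snapshot."""

    time: np.ndarray
    desired: np.ndarray       # n x 2, deg (FE, RUD)
    actual: np.ndarray        # n x 2, deg
    forces: np.ndarray        # n x 6, N (actual cable tensions)
    desired_forces: np.ndarray  # n x 6, N (controller targets)
    commands: np.ndarray      # n x 6, mm
    modes: np.ndarray         # n x 6, str
    muscle_names: tuple[str, ...]
    completed: bool
    seed: int
    strategy: str
    orientation: str
    motion: str
    loop_period: float
    spec: TrajectorySpec | None = None


@dataclass
class MetricsReport:
    mean_err_fe: float
    mean_err_rud: float
    mean_err_inplane: float
    mean_err_outplane: float
    percent_err: float
    max_flexion: float
    max_extension: float
    max_ulnar: float
    max_radial: float
    mean_force: dict
    completed: bool
    repeat_sd: float | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        return d


def run_simulation(plant_cfg: PlantConfig, ctrl_cfg: ControllerConfig,
                   spec: TrajectorySpec, seed: int,
                   muscles: MuscleSet | None = None,
                   force_profile: ForceProfile | None = None,
                   stop_on_limit: bool = True) -> SimulationResult:
    """Run one closed-loop simulation at the control rate.

    Steps the plant and the configured controller for ``spec.n_cycles``
    cycles, recording desired/actual angles, cable forces, commands and
    per-muscle modes. ``completed`` is False if a joint limit is hit or the
    state diverges — the virtual analogue of a motion the rig could not
    finish.
    """
    if muscles is None:
        muscles = default_muscles()
    traj = make_trajectory(spec, plant_cfg.loop_period, plant_cfg.limits_deg)
    plant = WristPlant(plant_cfg, muscles)
    # start at the trajectory's initial posture, cables just taut — the
    # virtual analogue of placing the hand at the start position
    plant.set_posture(traj[0].theta_fe_d, traj[0].theta_rud_d)
    ctrl = make_controller(ctrl_cfg, muscles, plant_cfg, force_profile)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    n = len(traj)
    m = len(muscles)
    time = np.empty(n)
    desired = np.empty((n, 2))
    actual = np.empty((n, 2))
    forces = np.empty((n, m))
    desired_f = np.empty((n, m))
    commands = np.empty((n, m))
    modes = np.empty((n, m), dtype=object)
    completed = True
    k_end = n
    for k, sample in enumerate(traj):
        meas_ang, meas_frc = plant.sense(rng)
        try:
            out = ctrl.step(sample, meas_ang, meas_frc)
            state = plant.step(out.actuator_cmd)
        except FloatingPointError:
            completed = False
            k_end = k
            break
        time[k] = sample.time
        desired[k] = (sample.theta_fe_d, sample.theta_rud_d)
        actual[k] = (state.wrist.theta_fe, state.wrist.theta_rud)
        forces[k] = state.cable_force
        desired_f[k] = out.desired_forces
        commands[k] = out.actuator_cmd
        modes[k] = out.mode
        if plant.limit_hit:
            completed = False
            k_end = k + 1
            if stop_on_limit:
                break
    sl = slice(0, k_end)
    return SimulationResult(
        time=time[sl], desired=desired[sl], actual=actual[sl],
        forces=forces[sl], desired_forces=desired_f[sl],
        commands=commands[sl], modes=modes[sl],
        muscle_names=muscles.names, completed=completed, seed=seed,
        strategy=ctrl_cfg.strategy, orientation=plant_cfg.orientation,
        motion=spec.motion, loop_period=plant_cfg.loop_period, spec=spec)


def _settled(result: SimulationResult, discard_cycles: int) -> np.ndarray:
    if result.spec is None:
        return np.ones(len(result.time), bool)
    t0 = discard_cycles * result.spec.period
    return result.time >= t0


def kinematic_error(result: SimulationResult, spec: TrajectorySpec,
                    discard_cycles: int = 1) -> MetricsReport:
    """Mean absolute desired-actual deviation per axis over the evaluated
    cycles (first ``discard_cycles`` discarded as settling).

    In-plane error averages the moved axes (both, for complex motions);
    out-of-plane averages the zero-amplitude axes (zero if none). The
    percent error normalizes the in-plane error by the principal motion
    amplitude.
    """
    if len(result.time) == 0:
        raise ValueError("empty time series")
    keep = _settled(result, discard_cycles)
    if keep.sum() < 2:
        raise ValueError("no samples left after discarding settling cycles")
    dev = np.abs(result.desired[keep] - result.actual[keep])
    err = dev.mean(axis=0)
    amps = np.array([spec.amp_fe, spec.amp_rud])
    moved = amps > 0
    inplane = float(err[moved].mean()) if moved.any() else float(err.mean())
    outplane = float(err[~moved].mean()) if (~moved).any() else 0.0
    amp = spec.moved_amplitude
    act = result.actual[keep]
    mean_force = {name: float(f) for name, f in
                  zip(result.muscle_names, result.forces[keep].mean(axis=0))}
    return MetricsReport(
        mean_err_fe=float(err[0]), mean_err_rud=float(err[1]),
        mean_err_inplane=inplane, mean_err_outplane=outplane,
        percent_err=float(100.0 * inplane / amp) if amp > 0 else 0.0,
        max_flexion=float(np.max(act[:, 0])),
        max_extension=float(np.max(-act[:, 0])),
        max_ulnar=float(np.max(act[:, 1])),
        max_radial=float(np.max(-act[:, 1])),
        mean_force=mean_force, completed=result.completed)


def repeatability(reports: list[MetricsReport]) -> float:
    """Repeatability: sample SD (ddof=1) of the mean in-plane error across
    repeated runs of the same condition."""
    if len(reports) < 2:
        raise ValueError("repeatability requires >= 2 repeats")
    return float(np.std([r.mean_err_inplane for r in reports], ddof=1))


def record_force_profiles(plant_cfg: PlantConfig, ctrl_cfg: ControllerConfig,
                          spec: TrajectorySpec, seed: int,
                          muscles: MuscleSet | None = None) -> ForceProfile:
    """Capture per-muscle force trajectories from a position-control run
    (downward orientation) for later replay by force control."""
    cfg = copy.deepcopy(plant_cfg)
    cfg.orientation = "downward"
    pos_cfg = copy.deepcopy(ctrl_cfg)
    pos_cfg.strategy = "position"
    res = run_simulation(cfg, pos_cfg, spec, seed, muscles)
    if not res.completed:
        raise RuntimeError("recording run did not complete")
    # keep the last full cycle (steady state) as the canonical profile
    keep = res.time >= (spec.n_cycles - 1) * spec.period
    t = res.time[keep]
    return ForceProfile(t - t[0], res.forces[keep])


def co_contraction_sweep(exp: ExperimentSpec, plant_cfg: PlantConfig,
                         ctrl_cfg: ControllerConfig,
                         spec: TrajectorySpec,
                         muscles: MuscleSet | None = None) -> pd.DataFrame:
    """Sweep the co-contraction handle (F0 for hybrid, rho for cascade).

    One full motion simulation per parameter value; tabulates per-muscle
    time-mean forces, the overall mean force and the kinematic error.
    """
    if exp.sweep is None:
        raise ValueError("ExperimentSpec.sweep must be set")
    param = exp.sweep["parameter"]
    if (param == "f0") != (ctrl_cfg.strategy == "hybrid"):
        if not (param == "rho" and ctrl_cfg.strategy == "cascade"):
            raise ValueError(f"sweep parameter {param!r} does not match "
                             f"strategy {ctrl_cfg.strategy!r}")
    if muscles is None:
        muscles = default_muscles()
    rows = []
    for value in exp.sweep["values"]:
        cc = copy.deepcopy(ctrl_cfg)
        setattr(cc, param, float(value))
        res = run_simulation(plant_cfg, cc, spec, exp.seed, muscles)
        row = {"parameter": param, "value": float(value),
               "completed": res.completed}
        if res.completed:
            rep = kinematic_error(res, spec)
            row.update({f"F_{k}": v for k, v in rep.mean_force.items()})
            row["mean_force"] = float(np.mean(list(rep.mean_force.values())))
            keep = _settled(res, 1)
            row["mean_desired_force"] = float(res.desired_forces[keep].mean())
            row["mean_err_inplane"] = rep.mean_err_inplane
        rows.append(row)
    return pd.DataFrame(rows)


def run_protocol(exp: ExperimentSpec, plant_cfg: PlantConfig,
                 ctrl_cfgs: dict[str, ControllerConfig],
                 muscles: MuscleSet | None = None,
                 trajectory_period: float = 4.0,
                 n_cycles: int = 3) -> pd.DataFrame:
    """Run the full cross product strategies x orientations x motions x
    repeats and emit a summary table (one row per condition: mean +/- SD
    error per axis, repeatability, max excursions, completion).

    Force control requires recorded profiles; they are captured once per
    motion from a position-control run when the 'force' strategy is listed
    (which itself requires a 'position' config to be present).
    """
    if muscles is None:
        muscles = default_muscles()
    profiles: dict[str, ForceProfile] = {}
    if "force" in exp.strategies:
        base = ctrl_cfgs.get("position")
        if base is None:
            raise ValueError("force strategy requires a 'position' config "
                             "to record input profiles")
        for motion in exp.motions:
            spec = TrajectorySpec(motion=motion, period=trajectory_period,
                                  n_cycles=n_cycles)
            profiles[motion] = record_force_profiles(
                plant_cfg, base, spec, exp.seed)

    rows = []
    for strategy in exp.strategies:
        cc = ctrl_cfgs[strategy]
        for orientation in exp.orientations:
            pc = copy.deepcopy(plant_cfg)
            pc.orientation = orientation
            for motion in exp.motions:
                spec = TrajectorySpec(motion=motion, period=trajectory_period,
                                      n_cycles=n_cycles)
                reports = []
                completed_all = True
                for rep_i in range(exp.repeats):
                    seed = exp.seed + 1000 * rep_i
                    res = run_simulation(pc, cc, spec, seed, muscles,
                                         force_profile=profiles.get(motion))
                    if res.completed:
                        reports.append(kinematic_error(res, spec))
                    else:
                        completed_all = False
                row = {"strategy": strategy, "orientation": orientation,
                       "motion": motion, "repeats": exp.repeats,
                       "completed": completed_all and len(reports) == exp.repeats}
                if reports:
                    for name in ("mean_err_fe", "mean_err_rud",
                                 "mean_err_inplane", "percent_err",
                                 "max_flexion", "max_extension",
                                 "max_ulnar", "max_radial"):
                        vals = [getattr(r, name) for r in reports]
                        row[name] = float(np.mean(vals))
                        row[name + "_sd"] = float(np.std(vals, ddof=1)) \
                            if len(vals) > 1 else 0.0
                    if len(reports) >= 2:
                        row["repeat_sd"] = repeatability(reports)
                rows.append(row)
    return pd.DataFrame(rows)
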