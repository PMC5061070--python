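"""Closed-loop control strategies for the tendon-driven wrist.

Four strategies, each a pure step function from (desired trajectory sample,
measurements, internal controller state) to per-muscle actuator commands:

- **position**: one PID per joint axis acting on the kinematic error; the
  corrective excursion is applied to the ECRB and distributed to the other
  tendons by moment-arm ratios, on top of the nominal excursions implied by
  the desired angles.
- **force**: per-muscle PI tracking of prescribed force trajectories
  (typically recorded from a position-control run); no position feedback.
- **hybrid**: position control with per-muscle force-bound overrides — a
  muscle whose force leaves the band [F0, F_max] is handed to a PI force
  loop targeting the violated bound until position control would take it
  back. F0 prevents complete cable unloading; F_max = 25 N/cm^2 x PCSA
  caps force at the physiological maximum.
- **cascade**: two axis PIDs (plus an inertial feedforward I * accel_d)
  produce joint torque demands; a quadratic optimization distributes them
  over the six muscles under the total-force (impedance) constraint
  sum F = rho; nested per-muscle PI loops track the optimized forces.

Per-axis position/torque PID gains are produced by the Ziegler-Nichols
routine in this module plus a documented derating.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .muscles import MuscleSet
from .plant import DEG, PlantConfig
from .qp import QPConfig, TorqueDemand, solve_force_distribution
from .trajectories import MotionSample

logger = logging.getLogger(__name__)

MODES = ("position", "force_low", "force_high", "force_track")


# --------------------------------------------------------------------- PID

@dataclass
class PIDGains:
    kp: float = 0.0
    ki: float = 0.0
    kd: float = 0.0
    integral_limit: float = 1e6   # clamp on |integral of error|
    deriv_filter_tau: float = 0.02  # s, first-order filter on the error

    def __post_init__(self) -> None:
        if min(self.kp, self.ki, self.kd) < 0:
            raise ValueError("PID gains must be nonnegative")
        if not self.integral_limit > 0:
            raise ValueError("integral_limit must be > 0")


@dataclass
class PIDState:
    integral: float = 0.0
    prev_error: float = 0.0
    filtered: float = 0.0
    initialized: bool = False


def pid_step(gains: PIDGains, st: PIDState, error: float,
             dt: float) -> tuple[float, PIDState]:
    """One discrete PID update.

    output = kp*e + ki*integral(e) + kd*d(filtered e)/dt, with trapezoidal
    integration clamped at ``integral_limit`` (anti-windup) and a
    first-order low-pass (time constant ``deriv_filter_tau``) on the error
    fed to the derivative term.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if not math.isfinite(error):
        raise ValueError("error must be finite")
    integral = st.integral + 0.5 * (error + st.prev_error) * dt
    integral = max(-gains.integral_limit, min(gains.integral_limit, integral))
    if st.initialized:
        a = dt / (gains.deriv_filter_tau + dt)
        filtered = st.filtered + a * (error - st.filtered)
        deriv = (filtered - st.filtered) / dt
    else:
        filtered = error
        deriv = 0.0
    out = gains.kp * error + gains.ki * integral + gains.kd * deriv
    return out, PIDState(integral=integral, prev_error=error,
                         filtered=filtered, initialized=True)


# ------------------------------------------------------------ configuration

@dataclass
class ControllerConfig:
    """Strategy selection, gains and force-bound handles.

    ``axis_gains`` are the two per-axis PIDs: in position/hybrid control
    the output is a corrective angle (deg per deg of error); in cascade it
    is a joint torque (N m per deg of error). ``force_gains`` is the
    per-muscle PI (kd forced to zero) whose output is an actuator
    displacement rate (mm/s per N of force error).
    """

    strategy: str = "hybrid"
    axis_gains: tuple[PIDGains, PIDGains] = field(
        default_factory=lambda: (PIDGains(), PIDGains()))
    force_gains: PIDGains | None = None  # strategy-resolved default
    f0: float = 10.0              # N, lower force bound (hybrid)
    f_max: np.ndarray | None = None  # N per muscle; default 25 x PCSA
    rho: float = 140.0            # N, cascade total-force constraint
    ff_gain: float = 1.0          # scale on the I*accel_d feedforward
    hysteresis_band: float = 2.0  # N, mode-switch deadband

    def __post_init__(self) -> None:
        if self.strategy not in ("position", "force", "hybrid", "cascade"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.f0 < 0:
            raise ValueError("f0 must be >= 0")
        if not self.rho > 0:
            raise ValueError("rho must be > 0")
        if self.force_gains is None:
            # per-strategy defaults: hybrid's floor/ceiling overrides need a
            # fast loop to catch a rapidly unloading cable; cascade's nested
            # tracking loops favour a gentler, less noise-amplifying one;
            # force replay (no position feedback) tolerates almost no
            # integral action, which double-integrates force error into
            # displacement and destabilizes the free pendulum
            self.force_gains = {
                "hybrid": PIDGains(kp=10.0, ki=100.0, integral_limit=50.0),
                "cascade": PIDGains(kp=2.0, ki=20.0, integral_limit=50.0),
                "force": PIDGains(kp=16.0, ki=8.0, integral_limit=50.0),
                "position": PIDGains(kp=2.0, ki=20.0, integral_limit=50.0),
            }[self.strategy]
        if self.force_gains.kd != 0.0:
            self.force_gains = replace(self.force_gains, kd=0.0)

    def validate_against(self, muscles: MuscleSet) -> None:
        f_max = self.resolved_f_max(muscles)
        if not self.f0 < f_max.min():
            raise ValueError(
                f"f0={self.f0} must be < min(f_max)={f_max.min()}")
        if self.rho < 6 * self.f0:
            warnings.warn("rho < 6*f0: the total-force constraint conflicts "
                          "with the per-muscle force floor", stacklevel=2)

    def resolved_f_max(self, muscles: MuscleSet) -> np.ndarray:
        if self.f_max is None:
            return muscles.f_max
        return np.broadcast_to(np.asarray(self.f_max, float),
                               (len(muscles),)).copy()


@dataclass
class ControlOutput:
    actuator_cmd: np.ndarray      # per-muscle reel-in command, mm
    desired_forces: np.ndarray    # per-muscle N (force-tracking modes)
    mode: tuple[str, ...]         # per-muscle, subset of MODES
    qp_feasible: bool = True


# ------------------------------------------------------------- controllers

class PositionController:
    """Per-axis PID position control with ECRB-normalized distribution.

    Nominal excursions from the desired angles are always commanded; the
    axis PID corrections are additive on top, applied to the ECRB directly
    and to the remaining tendons scaled by the moment-arm ratios
    r_ij / r_ECRB,j.
    """

    def __init__(self, cc: ControllerConfig, muscles: MuscleSet,
                 plant_cfg: PlantConfig):
        self.cc = cc
        self.muscles = muscles
        self.dt = plant_cfg.loop_period
        self._R = muscles.moment_arms  # mm
        i_ecrb = muscles.index("ECRB")
        if np.any(self._R[i_ecrb] == 0.0):
            raise ValueError("ECRB moment arm is zero on a commanded axis; "
                             "the correction distribution is undefined")
        self._axis_state = [PIDState(), PIDState()]

    def reset(self) -> None:
        self._axis_state = [PIDState(), PIDState()]

    def step(self, sample: MotionSample, meas_angles: np.ndarray,
             meas_forces: np.ndarray) -> ControlOutput:
        desired = np.array([sample.theta_fe_d, sample.theta_rud_d])
        err = desired - np.asarray(meas_angles, float)
        u = np.empty(2)  # corrective angle per axis, deg
        for j in range(2):
            u[j], self._axis_state[j] = pid_step(
                self.cc.axis_gains[j], self._axis_state[j], err[j], self.dt)
        nominal = self._R @ (desired * DEG)      # mm
        correction = self._R @ (u * DEG)         # ECRB direct, others by ratio
        return ControlOutput(actuator_cmd=nominal + correction,
                             desired_forces=np.zeros(len(self.muscles)),
                             mode=("position",) * len(self.muscles))


class _ForceLoop:
    """Per-muscle PI force tracking integrated to a displacement command."""

    def __init__(self, gains: PIDGains, n: int, dt: float):
        self.gains = replace(gains, kd=0.0)
        self.dt = dt
        self.states = [PIDState() for _ in range(n)]
        self.cmd = np.zeros(n)  # mm

    def reset_muscle(self, i: int, cmd: float) -> None:
        self.states[i] = PIDState()
        self.cmd[i] = cmd

    def track(self, i: int, f_desired: float, f_measured: float) -> float:
        rate, self.states[i] = pid_step(self.gains, self.states[i],
                                        f_desired - f_measured, self.dt)
        self.cmd[i] += rate * self.dt
        return self.cmd[i]


class ForceController:
    """Open-kinematics force control: replay prescribed per-muscle force
    trajectories through PI loops (derivative term zero). No position
    feedback — accuracy relies on the plant being gravitationally stable."""

    def __init__(self, cc: ControllerConfig, muscles: MuscleSet,
                 plant_cfg: PlantConfig, profile):
        self.cc = cc
        self.muscles = muscles
        self.profile = profile  # callable t -> per-muscle desired forces, N
        self._loop = _ForceLoop(cc.force_gains, len(muscles), plant_cfg.loop_period)
        self._warned = False
        self._primed = False

    def reset(self) -> None:
        self._loop = _ForceLoop(self.cc.force_gains, len(self.muscles),
                                self._loop.dt)
        self._primed = False

    def step(self, sample: MotionSample, meas_angles: np.ndarray,
             meas_forces: np.ndarray) -> ControlOutput:
        if not self._primed:
            # start from the excursions of the current (measured) posture so
            # the first commands do not yank the cables
            self._loop.cmd[:] = self.muscles.moment_arms @ (
                np.asarray(meas_angles, float) * DEG)
            self._primed = True
        fd = np.asarray(self.profile(sample.time), float)
        if np.any(fd < 0):
            if not self._warned:
                warnings.warn("negative desired force clamped to 0",
                              stacklevel=2)
                self._warned = True
            fd = np.maximum(fd, 0.0)
        cmd = np.array([self._loop.track(i, fd[i], meas_forces[i])
                        for i in range(len(self.muscles))])
        return ControlOutput(actuator_cmd=cmd, desired_forces=fd,
                             mode=("force_track",) * len(self.muscles))


class HybridController:
    """Position control with per-muscle force-bound overrides.

    Two PI force loops per muscle run alongside position control: a floor
    loop targeting F0 and a ceiling loop targeting F_max. Their commands
    act as override selectors — the actuator takes
    ``min(max(y_position, y_floor), y_ceiling)`` — so the floor loop only
    ever adds tension (it can never fight position control downward) and
    the ceiling loop only ever releases it. An idle override is kept primed
    one hysteresis band (in displacement terms, band / cable stiffness)
    away from the position command, making every takeover bumpless; its PI
    state is reset while idle (conditional integration, no windup).
    A muscle's mode is ``force_low``/``force_high`` while the corresponding
    override is winning, with a small labeling hysteresis against chatter.
    """

    def __init__(self, cc: ControllerConfig, muscles: MuscleSet,
                 plant_cfg: PlantConfig):
        cc.validate_against(muscles)
        self.cc = cc
        self.muscles = muscles
        self.pos = PositionController(cc, muscles, plant_cfg)
        self.f_max = cc.resolved_f_max(muscles)
        n = len(muscles)
        self._floor = _ForceLoop(cc.force_gains, n, plant_cfg.loop_period)
        self._ceil = _ForceLoop(cc.force_gains, n, plant_cfg.loop_period)
        self._ceil.cmd[:] = np.inf
        self.modes = ["position"] * n
        # displacement equivalent of the force hysteresis band
        self._band_mm = cc.hysteresis_band / (plant_cfg.cable_stiffness * 1e-3)
        self.switch_count = np.zeros(n, int)
        # a label change requires the new winner to persist this long
        # (debounce against sensor noise at a selector crossover)
        self.label_dwell_ticks = 20
        self._pending = ["position"] * n
        self._pending_ticks = np.zeros(n, int)

    def reset(self) -> None:
        n = len(self.muscles)
        self.pos.reset()
        self._floor = _ForceLoop(self.cc.force_gains, n, self._floor.dt)
        self._ceil = _ForceLoop(self.cc.force_gains, n, self._ceil.dt)
        self._ceil.cmd[:] = np.inf
        self.modes = ["position"] * n
        self.switch_count[:] = 0
        self._pending = ["position"] * n
        self._pending_ticks[:] = 0

    def step(self, sample: MotionSample, meas_angles: np.ndarray,
             meas_forces: np.ndarray) -> ControlOutput:
        cc = self.cc
        pos_out = self.pos.step(sample, meas_angles, meas_forces)
        n = len(self.muscles)
        cmd = np.empty(n)
        fd = np.zeros(n)
        eps = 0.5 * self._band_mm  # labeling hysteresis
        for i in range(n):
            f = meas_forces[i]
            y_pos = pos_out.actuator_cmd[i]
            y_floor = self._floor.track(i, cc.f0, f)
            if y_floor < y_pos:
                # idle: keep primed flush with the position command so a
                # takeover loses no time closing a displacement gap
                self._floor.reset_muscle(i, y_pos)
                y_floor = y_pos
            low_winner = max(y_pos, y_floor)
            y_ceil = self._ceil.track(i, self.f_max[i], f)
            if y_ceil > low_winner:
                self._ceil.reset_muscle(i, low_winner)
                y_ceil = low_winner
            cmd[i] = min(low_winner, y_ceil)
            # raw winner this tick: which selector produced the command
            if y_ceil < low_winner - eps:
                raw = "force_high"
            elif y_floor > y_pos + eps:
                raw = "force_low"
            else:
                raw = "position"
            # debounce: adopt the raw winner only after it persists
            if raw == self.modes[i]:
                self._pending_ticks[i] = 0
            elif raw == self._pending[i]:
                self._pending_ticks[i] += 1
                if self._pending_ticks[i] >= self.label_dwell_ticks:
                    self.modes[i] = raw
                    self.switch_count[i] += 1
                    self._pending_ticks[i] = 0
            else:
                self._pending[i] = raw
                self._pending_ticks[i] = 1
            if self.modes[i] == "force_low":
                fd[i] = cc.f0
            elif self.modes[i] == "force_high":
                fd[i] = self.f_max[i]
        return ControlOutput(actuator_cmd=cmd, desired_forces=fd,
                             mode=tuple(self.modes))


class CascadeController:
    """Torque PIDs -> quadratic force distribution -> per-muscle PI loops.

    The two axis PIDs output joint torques (N m); an inertial feedforward
    ``ff_gain * I_j * accel_d`` anticipates points of maximum acceleration.
    The QP distributes the torques over the muscles under sum F = rho; six
    PI loops track the optimized forces.
    """

    def __init__(self, cc: ControllerConfig, muscles: MuscleSet,
                 plant_cfg: PlantConfig):
        cc.validate_against(muscles)
        self.cc = cc
        self.muscles = muscles
        self.plant_cfg = plant_cfg
        self.qp_cfg = QPConfig(rho=cc.rho)
        self._axis_state = [PIDState(), PIDState()]
        self._loop = _ForceLoop(cc.force_gains, len(muscles), plant_cfg.loop_period)
        self.infeasible_ticks = 0
        self._primed = False

    def reset(self) -> None:
        self._axis_state = [PIDState(), PIDState()]
        self._loop = _ForceLoop(self.cc.force_gains, len(self.muscles),
                                self._loop.dt)
        self.infeasible_ticks = 0
        self._primed = False

    def step(self, sample: MotionSample, meas_angles: np.ndarray,
             meas_forces: np.ndarray) -> ControlOutput:
        if not self._primed:
            self._loop.cmd[:] = self.muscles.moment_arms @ (
                np.asarray(meas_angles, float) * DEG)
            self._primed = True
        desired = np.array([sample.theta_fe_d, sample.theta_rud_d])
        accel = np.array([sample.accel_fe_d, sample.accel_rud_d]) * DEG  # rad/s^2
        err = desired - np.asarray(meas_angles, float)
        torque = np.empty(2)
        for j in range(2):
            fb, self._axis_state[j] = pid_step(
                self.cc.axis_gains[j], self._axis_state[j], err[j],
                self.plant_cfg.loop_period)
            torque[j] = fb + self.cc.ff_gain * self.plant_cfg.inertia[j] * accel[j]
        sol = solve_force_distribution(TorqueDemand(torque[0], torque[1]),
                                       self.muscles, self.qp_cfg)
        if not sol.feasible:
            self.infeasible_ticks += 1
            logger.debug("QP infeasible at t=%.3f: residuals=%s",
                         sample.time, sol.residuals)
        cmd = np.array([self._loop.track(i, sol.forces[i], meas_forces[i])
                        for i in range(len(self.muscles))])
        return ControlOutput(actuator_cmd=cmd, desired_forces=sol.forces,
                             mode=("force_track",) * len(self.muscles),
                             qp_feasible=sol.feasible)


def make_controller(cc: ControllerConfig, muscles: MuscleSet,
                    plant_cfg: PlantConfig, force_profile=None):
    """Instantiate the controller named by ``cc.strategy``."""
    if cc.strategy == "position":
        return PositionController(cc, muscles, plant_cfg)
    if cc.strategy == "force":
        if force_profile is None:
            raise ValueError("force strategy requires a recorded force profile")
        return ForceController(cc, muscles, plant_cfg, force_profile)
    if cc.strategy == "hybrid":
        return HybridController(cc, muscles, plant_cfg)
    return CascadeController(cc, muscles, plant_cfg)


class ForceProfile:
    """Recorded per-muscle force trajectories, linearly interpolated in
    time and periodically extended — replayable by force control."""

    def __init__(self, times: np.ndarray, forces: np.ndarray):
        self.times = np.asarray(times, float)
        self.forces = np.asarray(forces, float)
        if self.forces.shape[0] != self.times.shape[0]:
            raise ValueError("times and forces must have matching lengths")
        self.duration = float(self.times[-1] - self.times[0])

    def __call__(self, t: float) -> np.ndarray:
        tq = self.times[0] + ((t - self.times[0]) % self.duration
                              if self.duration > 0 else 0.0)
        return np.array([np.interp(tq, self.times, self.forces[:, i])
                         for i in range(self.forces.shape[1])])

    def to_csv(self, path, names) -> None:
        import pandas as pd
        df = pd.DataFrame(self.forces, columns=[f"F_{n}" for n in names])
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ForceProfile":
        import pandas as pd
        df = pd.read_csv(path)
        fcols = [c for c in df.columns if c.startswith("F_")]
        return cls(df["time"].to_numpy(), df[fcols].to_numpy())


# ------------------------------------------------------- Ziegler-Nichols

@dataclass
class ZNSearchConfig:
    """Search settings for the ultimate-gain experiment and the documented
    post-tuning derating (the 'manual adjustment' applied to the classic
    table values to trade response speed for low overshoot and noise
    amplification)."""

    kp_min: float = 0.02
    kp_max: float = 4096.0
    step_deg: float = 2.0       # setpoint step used to excite oscillation
    sim_time: float = 3.0       # s per probe
    n_bisect: int = 12
    amp_cap_factor: float = 1.0  # tail amplitude > this x step => unstable
    derate_kp: float = 0.45
    derate_ki: float = 0.45
    derate_kd: float = 0.45
    integral_limit: float = 60.0


def find_ultimate_gain(run_closed_loop, cfg: ZNSearchConfig,
                       y_scale: float | None = None) -> tuple[float, float]:
    """Locate the ultimate gain K_u and period T_u of a proportional-only
    loop by bisection on the onset of non-decaying oscillation.

    ``run_closed_loop(kp)`` must simulate the P-only closed loop against a
    step setpoint and return (t, y) arrays. A response is unstable when the
    oscillation amplitude in the last third of the record is at least that
    of the middle third, or when the tail amplitude exceeds
    ``amp_cap_factor * y_scale`` (a saturated limit cycle counts as
    instability — a physical rig never grows without bound).
    """
    if y_scale is None:
        y_scale = cfg.step_deg

    def probe(kp: float) -> tuple[bool, np.ndarray, np.ndarray]:
        t, y = run_closed_loop(kp)
        n = len(y)
        mid, last = y[n // 3: 2 * n // 3], y[2 * n // 3:]
        a_mid = np.max(np.abs(mid - np.mean(mid)))
        a_last = np.max(np.abs(last - np.mean(last)))
        if a_last > cfg.amp_cap_factor * y_scale:
            return True, t, y
        if a_mid <= 1e-12:
            return False, t, y
        return a_last / a_mid >= 1.0, t, y

    # grow kp geometrically until the oscillation no longer decays
    lo, hi = None, None
    kp = cfg.kp_min
    while kp <= cfg.kp_max:
        unstable, t, y = probe(kp)
        if unstable:
            hi = kp
            break
        lo = kp
        kp *= 2.0
    if hi is None:
        raise RuntimeError("no sustained oscillation found below kp_max: "
                           "the loop has no ultimate gain in range")
    if lo is None:
        raise RuntimeError("loop already unstable at kp_min")
    for _ in range(cfg.n_bisect):
        kp = math.sqrt(lo * hi)
        unstable, _, _ = probe(kp)
        if unstable:
            hi = kp
        else:
            lo = kp
    ku = math.sqrt(lo * hi)
    # period from zero crossings of the sustained oscillation just past K_u
    _, t, y = probe(hi)
    n = len(y)
    tail = y[n // 2:] - np.mean(y[n // 2:])
    tt = t[n // 2:]
    sign = np.sign(tail)
    crossings = tt[1:][np.diff(sign) != 0]
    if len(crossings) < 3:
        raise RuntimeError("too few zero crossings to estimate the "
                           "ultimate period")
    tu = 2.0 * float(np.mean(np.diff(crossings)))
    return ku, tu


def ziegler_nichols_tune(plant_factory, axis: int,
                         cfg: ZNSearchConfig | None = None,
                         torque_mode: bool = False) -> PIDGains:
    """Tune one axis PID on the virtual plant.

    Probes the proportional-only loop (position-control distribution, or
    direct torque actuation when ``torque_mode``) with a small setpoint
    step on a fresh, noise-free, downward-oriented plant from
    ``plant_factory()``; classic table gains (kp = 0.6 Ku, ki = 2 kp / Tu,
    kd = kp Tu / 8) are then derated by the configured factors.
    """
    if cfg is None:
        cfg = ZNSearchConfig()

    def run(kp: float) -> tuple[np.ndarray, np.ndarray]:
        plant, muscles = plant_factory()
        plant.cfg.angle_noise_sd = 0.0
        plant.cfg.force_noise_sd = 0.0
        if plant.cfg.orientation != "downward":
            raise ValueError("Ziegler-Nichols probing requires the "
                             "gravitationally stable (downward) orientation")
        dt = plant.cfg.loop_period
        n = int(cfg.sim_time / dt)
        R = muscles.moment_arms
        target = np.zeros(2)
        target[axis] = cfg.step_deg
        ts = np.empty(n)
        ys = np.empty(n)
        if torque_mode:
            loop = _ForceLoop(PIDGains(kp=2.0, ki=20.0), len(muscles), dt)
            qp_cfg = QPConfig(rho=140.0)
        for k in range(n):
            st = plant.state.wrist
            ang = np.array([st.theta_fe, st.theta_rud])
            err = target - ang
            if torque_mode:
                demand = np.zeros(2)
                demand[axis] = kp * err[axis]
                sol = solve_force_distribution(
                    TorqueDemand(demand[0], demand[1]), muscles, qp_cfg)
                frc = plant.state.cable_force
                cmd = np.array([loop.track(i, sol.forces[i], frc[i])
                                for i in range(len(muscles))])
            else:
                u = np.zeros(2)
                u[axis] = kp * err[axis]
                cmd = R @ (target * DEG) + R @ (u * DEG)
            plant.step(cmd, dt)
            ts[k] = plant.state.wrist.time
            ys[k] = [plant.state.wrist.theta_fe, plant.state.wrist.theta_rud][axis]
        return ts, ys

    ku, tu = find_ultimate_gain(run, cfg)
    kp = 0.6 * ku * cfg.derate_kp
    ki = 2.0 * (0.6 * ku) / tu * cfg.derate_ki
    kd = (0.6 * ku) * tu / 8.0 * cfg.derate_kd
    return PIDGains(kp=kp, ki=ki, kd=kd, integral_limit=cfg.integral_limit)


#: Per-strategy tuning presets: the documented manual adjustment applied on
#: top of the classic table values. Hybrid tolerates (and needs, for
#: disturbance rejection against its force-floor overrides) twice the
#: integral gain, because the engaged floor loops keep antagonist cables
#: taut and stiffen the position loop; position and cascade are run at the
#: plain derated values.
STRATEGY_TUNING: dict[str, ZNSearchConfig] = {
    "position": ZNSearchConfig(),
    "hybrid": ZNSearchConfig(derate_ki=0.9, derate_kd=3.6),
    "cascade": ZNSearchConfig(),
}


def tune_default_gains(plant_factory) -> dict[str, tuple[PIDGains, PIDGains]]:
    """Produce the per-strategy axis gains by Ziegler-Nichols probing of
    the plant from ``plant_factory`` (position/hybrid: excursion loop;
    cascade: torque loop), with the per-strategy adjustments of
    ``STRATEGY_TUNING``."""
    out: dict[str, tuple[PIDGains, PIDGains]] = {}
    for strategy, cfg in STRATEGY_TUNING.items():
        torque = strategy == "cascade"
        out[strategy] = tuple(
            ziegler_nichols_tune(plant_factory, axis, cfg, torque_mode=torque)
            for axis in (0, 1))
    return out
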