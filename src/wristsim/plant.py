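"""Virtual 2-DOF tendon-driven wrist plant.

The physical rig — phantom hand, pulleys, linear actuators, load cells and
motion capture — is replaced by a rigid-body model with decoupled
flexion-extension (FE) and radioulnar-deviation (RUD) axes:

    I_j * theta_dd_j = T_muscle_j + T_gravity_j - b_j * theta_d_j

Tendons are pull-only cables with one-sided series elasticity: the tension
in cable i is ``F_i = max(0, k * (y_i - e_i(theta)))`` where ``y_i`` is the
actuator reel-in displacement and ``e_i`` the tendon excursion required by
the current joint posture. Actuators are rate-limited position servos.
Sensing (joint angles, cable forces) is the truth plus additive Gaussian
noise.

Angles are degrees at every public interface and radians internally;
actuator displacements and moment arms are millimetres at the interface,
metres internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .muscles import MuscleSet

DEG = math.pi / 180.0


@dataclass
class PlantConfig:
    """Physical parameters of the virtual wrist rig.

    Inertial values emulate a 50th-percentile male hand (they are fixture
    defaults, configurable, not measured quantities). ``orientation`` is the
    hanging direction of the hand relative to gravity: ``downward`` (hand
    below the elbow; gravity is restoring) or ``upward`` (hand above the
    elbow; gravity is destabilizing, an inverted pendulum).
    """

    hand_mass: float = 0.45          # kg
    cog_offset: float = 0.06         # m, wrist center to hand center of gravity
    inertia_fe: float = 2.0e-3       # kg m^2
    inertia_rud: float = 2.0e-3      # kg m^2
    damping_fe: float = 2.0e-2       # N m s / rad (cable/pulley/bearing friction)
    damping_rud: float = 2.0e-2      # N m s / rad
    orientation: str = "downward"    # {"upward", "downward"}
    gravity: float = 9.81            # m / s^2
    cable_stiffness: float = 2.0e4   # N / m
    actuator_max_speed: float = 0.1  # m / s
    loop_period: float = 0.005       # s, control tick
    physics_substep: float = 0.001   # s, internal integration step
    angle_noise_sd: float = 0.1      # deg, motion-capture noise
    force_noise_sd: float = 0.1      # N, load-cell noise
    joint_limits_fe: tuple[float, float] = (-75.0, 75.0)   # deg
    joint_limits_rud: tuple[float, float] = (-25.0, 25.0)  # deg

    def __post_init__(self) -> None:
        for name in ("hand_mass", "cog_offset", "inertia_fe", "inertia_rud",
                     "gravity", "cable_stiffness", "actuator_max_speed",
                     "loop_period", "physics_substep"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("damping_fe", "damping_rud",
                     "angle_noise_sd", "force_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.orientation not in ("upward", "downward"):
            raise ValueError(f"orientation must be 'upward' or 'downward', "
                             f"got {self.orientation!r}")
        for name in ("joint_limits_fe", "joint_limits_rud"):
            lo, hi = getattr(self, name)
            if not lo < 0 < hi:
                raise ValueError(f"{name} must bracket the neutral posture")

    @property
    def inertia(self) -> np.ndarray:
        return np.array([self.inertia_fe, self.inertia_rud])

    @property
    def damping(self) -> np.ndarray:
        return np.array([self.damping_fe, self.damping_rud])

    @property
    def limits_deg(self) -> np.ndarray:
        return np.array([self.joint_limits_fe, self.joint_limits_rud])


@dataclass
class WristState:
    """Joint-space state: angles (deg), angular velocities (deg/s), time (s)."""

    theta_fe: float = 0.0
    theta_rud: float = 0.0
    omega_fe: float = 0.0
    omega_rud: float = 0.0
    time: float = 0.0


@dataclass
class PlantState:
    """Full plant state: wrist kinematics, actuator reel-in (mm) and cable
    tensions (N, nonnegative) for the six muscles."""

    wrist: WristState = field(default_factory=WristState)
    actuator_pos: np.ndarray = field(default_factory=lambda: np.zeros(6))
    cable_force: np.ndarray = field(default_factory=lambda: np.zeros(6))


def gravity_torque(wrist: WristState, cfg: PlantConfig) -> tuple[float, float]:
    """Gravity torque (N m) about each axis for the current posture.

    Downward (hand hanging): restoring pendulum torque ``-m g d sin(theta)``
    per axis. Upward (hand above elbow): destabilizing inverted-pendulum
    torque ``+m g d sin(theta)``. Zero at neutral.
    """
    mgd = cfg.hand_mass * cfg.gravity * cfg.cog_offset
    sign = -1.0 if cfg.orientation == "downward" else 1.0
    t_fe = sign * mgd * math.sin(wrist.theta_fe * DEG)
    t_rud = sign * mgd * math.sin(wrist.theta_rud * DEG)
    return t_fe, t_rud


def muscle_torques(forces: np.ndarray, muscles: MuscleSet) -> tuple[float, float]:
    """Net joint torque (N m) from cable tensions: ``T_j = sum_i r_ij F_i``.

    Moment arms are mm and converted to metres. Negative forces are
    rejected — cables pull only.
    """
    forces = np.asarray(forces, float)
    if forces.shape != (len(muscles),):
        raise ValueError(f"expected {len(muscles)} forces, got {forces.shape}")
    if np.any(forces < 0):
        raise ValueError("cable forces must be nonnegative")
    t = (muscles.moment_arms * 1e-3).T @ forces
    return float(t[0]), float(t[1])


def tendon_excursion(wrist: WristState, muscles: MuscleSet) -> np.ndarray:
    """Tendon excursion (mm) of each muscle at the given posture.

    Constant-moment-arm linear model: ``e_i = r_i,fe * theta_fe +
    r_i,rud * theta_rud`` with angles in radians. Positive excursion is
    shortening of the tendon path toward that muscle's positive-torque
    direction, i.e. the reel-in the actuator must provide to keep the cable
    just taut.
    """
    theta = np.array([wrist.theta_fe, wrist.theta_rud]) * DEG
    return muscles.moment_arms @ theta


class WristPlant:
    """Stateful virtual wrist: integrates the dynamics and provides noisy
    measurements.

    Parameters
    ----------
    cfg : PlantConfig
    muscles : MuscleSet
    state : PlantState, optional
        Initial state (neutral, at rest, cables just taut by default).
    """

    def __init__(self, cfg: PlantConfig, muscles: MuscleSet,
                 state: PlantState | None = None):
        self.cfg = cfg
        self.muscles = muscles
        self._R_m = muscles.moment_arms * 1e-3  # n x 2, metres
        if state is None:
            state = PlantState()
        self._theta = np.array([state.wrist.theta_fe, state.wrist.theta_rud]) * DEG
        self._omega = np.array([state.wrist.omega_fe, state.wrist.omega_rud]) * DEG
        self._act = np.asarray(state.actuator_pos, float) * 1e-3  # m
        self._time = state.wrist.time
        self.limit_hit = False

    # ------------------------------------------------------------------ state

    @property
    def state(self) -> PlantState:
        wrist = WristState(
            theta_fe=self._theta[0] / DEG, theta_rud=self._theta[1] / DEG,
            omega_fe=self._omega[0] / DEG, omega_rud=self._omega[1] / DEG,
            time=self._time,
        )
        return PlantState(wrist=wrist, actuator_pos=self._act * 1e3,
                          cable_force=self._forces())

    def _forces(self) -> np.ndarray:
        slack = self._act - self._R_m @ self._theta  # m
        return np.maximum(0.0, self.cfg.cable_stiffness * slack)

    # --------------------------------------------------------------- dynamics

    def step(self, actuator_cmd: np.ndarray, dt: float | None = None) -> PlantState:
        """Advance the plant by one control period.

        ``actuator_cmd`` is the commanded reel-in per muscle in mm. The
        command is held for the whole period while the physics integrates
        with symplectic-Euler substeps; actuators slew toward the command at
        ``actuator_max_speed``. Joint limits are hard stops (velocity zeroed,
        ``limit_hit`` latched).
        """
        cfg = self.cfg
        if dt is None:
            dt = cfg.loop_period
        if not dt > 0:
            raise ValueError(f"dt must be > 0, got {dt}")
        cmd = np.asarray(actuator_cmd, float) * 1e-3  # m
        if cmd.shape != self._act.shape or not np.all(np.isfinite(cmd)):
            raise ValueError("actuator command must be finite, one per muscle")
        if not (np.all(np.isfinite(self._theta)) and np.all(np.isfinite(self._omega))):
            raise FloatingPointError(
                f"plant state non-finite at t={self._time:.3f}s: "
                f"theta={self._theta}, omega={self._omega}")

        n_sub = max(1, round(dt / cfg.physics_substep))
        h = dt / n_sub
        mgd = cfg.hand_mass * cfg.gravity * cfg.cog_offset
        g_sign = -1.0 if cfg.orientation == "downward" else 1.0
        lim = cfg.limits_deg * DEG
        max_step = cfg.actuator_max_speed * h

        for _ in range(n_sub):
            # actuator: rate-limited position servo
            self._act += np.clip(cmd - self._act, -max_step, max_step)
            forces = self._forces()
            t_muscle = self._R_m.T @ forces
            t_grav = g_sign * mgd * np.sin(self._theta)
            acc = (t_muscle + t_grav - cfg.damping * self._omega) / cfg.inertia
            self._omega += h * acc
            self._theta += h * self._omega
            below, above = self._theta < lim[:, 0], self._theta > lim[:, 1]
            if below.any() or above.any():
                self.limit_hit = True
                self._theta = np.clip(self._theta, lim[:, 0], lim[:, 1])
                self._omega[below | above] = 0.0
            self._time += h

        return self.state

    # ---------------------------------------------------------------- sensing

    def sense(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Noisy measurement: (angles deg [fe, rud], per-muscle forces N).

        Additive Gaussian noise with the configured standard deviations,
        drawn from ``rng``; identical seeds give identical streams.
        """
        ang = self._theta / DEG + rng.normal(0.0, self.cfg.angle_noise_sd, 2)
        frc = self._forces() + rng.normal(0.0, self.cfg.force_noise_sd,
                                          len(self.muscles))
        return ang, frc

    # ------------------------------------------------------------- utilities

    def set_posture(self, theta_fe: float, theta_rud: float,
                    taut: bool = True) -> None:
        """Teleport to a posture (deg), at rest.

        With ``taut`` the actuators are placed so every cable is exactly at
        zero tension; otherwise they are paid far out so every cable stays
        slack anywhere inside the joint limits (a free, passive joint).
        """
        self._theta = np.array([theta_fe, theta_rud]) * DEG
        self._omega[:] = 0.0
        if taut:
            self._act = self._R_m @ self._theta
        else:
            self._act = self._R_m @ self._theta - 0.05  # 50 mm of slack


def estimate_moment_arms(plant: WristPlant, angle_range: float = 15.0,
                         n_samples: int = 31,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Recover the 6x2 moment-arm matrix (mm) by tendon excursion tests.

    One axis is swept at a time over ``[-angle_range, +angle_range]`` deg
    while the other is held at neutral; the moment arm is the least-squares
    slope of tendon excursion versus (measured) joint angle. With a
    noise-free plant the recovery is exact because the plant's excursion
    model is linear.
    """
    if not (angle_range * 2 >= 10.0 and n_samples >= 10):
        raise ValueError("sweep must cover >= 10 deg with >= 10 samples")
    lim = plant.cfg.limits_deg
    if angle_range > min(lim[:, 1].min(), -lim[:, 0].max()):
        raise ValueError("sweep exceeds joint limits")
    angles = np.linspace(-angle_range, angle_range, n_samples)
    R = np.empty((len(plant.muscles), 2))
    for axis in range(2):
        exc = np.empty((n_samples, len(plant.muscles)))
        meas = np.empty(n_samples)
        for k, a in enumerate(angles):
            pose = (a, 0.0) if axis == 0 else (0.0, a)
            plant.set_posture(*pose)
            exc[k] = tendon_excursion(plant.state.wrist, plant.muscles)
            noise = 0.0 if rng is None else rng.normal(0.0, plant.cfg.angle_noise_sd)
            meas[k] = a + noise
        x = meas * DEG
        x = x - x.mean()
        if np.dot(x, x) == 0:
            raise ValueError("degenerate sweep: zero angle variance")
        R[:, axis] = (exc - exc.mean(axis=0)).T @ x / np.dot(x, x)
    plant.set_posture(0.0, 0.0)
    return R
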