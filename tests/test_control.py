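import math
from dataclasses import replace

import numpy as np
import pytest

import wristsim as ws
from wristsim.control import (ControllerConfig, HybridController, PIDGains,
                              PIDState, PositionController, ZNSearchConfig,
                              find_ultimate_gain, make_controller, pid_step)
from wristsim.plant import DEG, PlantConfig
from wristsim.trajectories import MotionSample


def sample(t=0.0, fe=0.0, rud=0.0, afe=0.0, arud=0.0):
    return MotionSample(time=t, theta_fe_d=fe, theta_rud_d=rud,
                        accel_fe_d=afe, accel_rud_d=arud)


# ------------------------------------------------------------------- PID

def test_pid_zero_error_stream_gives_zero_output():
    gains = PIDGains(kp=1.0, ki=1.0, kd=1.0)
    st = PIDState()
    for _ in range(5):
        out, st = pid_step(gains, st, 0.0, 0.01)
        assert out == 0.0
    assert st.integral == 0.0


def test_pid_pure_proportional():
    out, _ = pid_step(PIDGains(kp=3.0), PIDState(), 2.0, 0.01)
    assert out == pytest.approx(6.0)


def test_pid_trapezoidal_accumulation_matches_hand_computation():
    gains = PIDGains(kp=1.0, ki=1.0, kd=0.0)
    st = PIDState()
    integral = 0.0
    prev = 0.0
    for _ in range(10):
        out, st = pid_step(gains, st, 1.0, 0.1)
        integral += 0.5 * (1.0 + prev) * 0.1  # independent trapezoid
        prev = 1.0
        assert out == pytest.approx(1.0 + integral, rel=1e-12)


def test_pid_integral_never_exceeds_clamp():
    gains = PIDGains(kp=0.0, ki=1.0, kd=0.0, integral_limit=0.5)
    st = PIDState()
    for _ in range(1000):  # persistent saturation
        _, st = pid_step(gains, st, 10.0, 0.1)
        assert abs(st.integral) <= 0.5


def test_pid_rejects_bad_inputs():
    with pytest.raises(ValueError):
        pid_step(PIDGains(), PIDState(), 1.0, 0.0)
    with pytest.raises(ValueError):
        pid_step(PIDGains(), PIDState(), math.nan, 0.01)


# ---------------------------------------------------------- configuration

def test_config_rejects_floor_above_ceiling(muscles):
    cc = ControllerConfig(strategy="hybrid", f0=50.0)
    with pytest.raises(ValueError, match="f_max"):
        cc.validate_against(muscles)


def test_config_warns_when_rho_conflicts_with_floor(muscles):
    cc = ControllerConfig(strategy="cascade", f0=30.0, rho=100.0)
    with pytest.warns(UserWarning, match="rho"):
        cc.validate_against(muscles)


def test_force_loop_derivative_term_forced_to_zero():
    cc = ControllerConfig(strategy="force",
                          force_gains=PIDGains(kp=1.0, ki=1.0, kd=5.0))
    assert cc.force_gains.kd == 0.0


# ------------------------------------------------------- position control

def test_zero_error_commands_nominal_excursions(muscles):
    pc = PlantConfig(angle_noise_sd=0.0)
    cc = ControllerConfig(strategy="position",
                          axis_gains=(PIDGains(kp=1.0), PIDGains(kp=1.0)))
    ctrl = PositionController(cc, muscles, pc)
    desired = sample(fe=15.0, rud=-5.0)
    measured = np.array([15.0, -5.0])  # no kinematic error
    out = ctrl.step(desired, measured, np.zeros(6))
    nominal = muscles.moment_arms @ (np.array([15.0, -5.0]) * DEG)
    np.testing.assert_allclose(out.actuator_cmd, nominal, atol=1e-12)
    assert set(out.mode) == {"position"}


def test_corrections_distributed_by_moment_arm_ratio(muscles):
    """With an FE-only error, each tendon's corrective excursion relates to
    ECRB's by r_i,fe / r_ECRB,fe."""
    pc = PlantConfig()
    cc = ControllerConfig(strategy="position",
                          axis_gains=(PIDGains(kp=2.0), PIDGains(kp=2.0)))
    ctrl = PositionController(cc, muscles, pc)
    out = ctrl.step(sample(fe=10.0), np.array([8.0, 0.0]), np.zeros(6))
    nominal = muscles.moment_arms @ (np.array([10.0, 0.0]) * DEG)
    corr = out.actuator_cmd - nominal
    i = muscles.index("ECRB")
    ratios = corr / corr[i]
    expected = muscles.moment_arms[:, 0] / muscles.moment_arms[i, 0]
    np.testing.assert_allclose(ratios, expected, rtol=1e-9)


def test_zero_ecrb_moment_arm_rejected_at_construction(muscles):
    bad = ws.MuscleSet([
        ws.MuscleParams(m.name, m.pcsa, m.r_fe,
                        0.0 if m.name == "ECRB" else m.r_rud)
        for m in muscles])
    with pytest.raises(ValueError, match="ECRB"):
        PositionController(ControllerConfig(strategy="position"), bad,
                           PlantConfig())


# --------------------------------------------------------- hybrid control

def test_hybrid_reduces_to_position_when_bounds_inactive(muscles, default_cfg):
    """With F0 = 0 and a huge F_max the overrides never engage and hybrid's
    commands equal pure position control's over a whole cycle."""
    pc = PlantConfig()
    gains = default_cfg.controllers["hybrid"].axis_gains
    cc_h = ControllerConfig(strategy="hybrid", axis_gains=gains, f0=0.0,
                            f_max=np.full(6, 1e9))
    cc_p = ControllerConfig(strategy="position", axis_gains=gains)
    hyb = make_controller(cc_h, muscles, pc)
    pos = make_controller(cc_p, muscles, pc)
    rng = np.random.default_rng(5)
    t = 0.0
    for _ in range(200):
        fe_d = 10.0 * math.sin(2 * math.pi * t / 4.0)
        meas_ang = np.array([fe_d - 0.5, 0.2]) + rng.normal(0, 0.1, 2)
        meas_f = np.abs(rng.normal(30.0, 1.0, 6))
        s = sample(t=t, fe=fe_d)
        out_h = hyb.step(s, meas_ang, meas_f)
        out_p = pos.step(s, meas_ang, meas_f)
        np.testing.assert_allclose(out_h.actuator_cmd, out_p.actuator_cmd,
                                   atol=1e-9)
        t += pc.loop_period


def test_hybrid_flags_muscle_below_floor(muscles, default_cfg):
    cc = replace(default_cfg.controllers["hybrid"])
    ctrl = HybridController(cc, muscles, PlantConfig())
    meas_f = np.full(6, 30.0)
    meas_f[1] = 5.0  # FCU measured below F0 = 10 N
    out = None
    # let the floor loop engage and the label debounce elapse
    for _ in range(ctrl.label_dwell_ticks + 5):
        out = ctrl.step(sample(), np.zeros(2), meas_f)
    assert out.mode[1] == "force_low"
    assert out.desired_forces[1] == pytest.approx(10.0)
    assert all(m == "position" for k, m in enumerate(out.mode) if k != 1)


def test_hybrid_keeps_cables_loaded_in_closed_loop(planar_runs, default_cfg):
    """Post-settling, no hybrid cable unloads: every force stays above
    F0 minus the hysteresis band (position control, by contrast, drops
    antagonists to exactly zero)."""
    from wristsim.protocols import _settled
    cc = default_cfg.controllers["hybrid"]
    tol = cc.hysteresis_band
    for motion in ("FE30", "RUD10"):
        res, _ = planar_runs[("hybrid", motion, "downward")]
        keep = _settled(res, 1)
        assert res.forces[keep].min() >= cc.f0 - tol
    res_pos, _ = planar_runs[("position", "FE30", "downward")]
    keep = _settled(res_pos, 1)
    assert res_pos.forces[keep].min() == pytest.approx(0.0, abs=1e-9)


def test_hybrid_mode_switches_bounded_in_steady_state(planar_runs):
    from wristsim.protocols import _settled
    res, _ = planar_runs[("hybrid", "FE30", "downward")]
    keep = _settled(res, 1)
    modes = res.modes[keep]
    switches = (modes[1:] != modes[:-1]).sum(axis=0)
    cycles = 2  # evaluated cycles after settling
    assert switches.max() <= 4 * cycles


# -------------------------------------------------------- cascade control

def test_cascade_zero_demand_returns_min_objective_forces(muscles, default_cfg):
    """Zero angle error and zero acceleration: the torque demand is zero and
    the commanded forces are the QP minimizer with sum F = rho."""
    pc = PlantConfig()
    cc = replace(default_cfg.controllers["cascade"])
    ctrl = make_controller(cc, muscles, pc)
    out = ctrl.step(sample(), np.zeros(2), np.zeros(6))
    expected = ws.solve_force_distribution(ws.TorqueDemand(0.0, 0.0), muscles,
                                           ws.QPConfig(rho=cc.rho))
    np.testing.assert_allclose(out.desired_forces, expected.forces, atol=1e-7)
    assert out.desired_forces.sum() == pytest.approx(cc.rho, abs=1e-6)
    assert set(out.mode) == {"force_track"}


def test_cascade_commanded_forces_satisfy_qp_constraints(planar_runs, muscles,
                                                         default_cfg):
    """Every tick: sum F = rho, nonnegativity. (The torque equality is
    checked implicitly: the QP returns feasible solutions whose torque
    residuals are at solver tolerance.)"""
    rho = default_cfg.controllers["cascade"].rho
    res, _ = planar_runs[("cascade", "FE30", "downward")]
    sums = res.desired_forces.sum(axis=1)
    np.testing.assert_allclose(sums, rho, atol=1e-6)
    assert res.desired_forces.min() >= -1e-9


def test_controller_outputs_are_deterministic(muscles, default_cfg):
    pc = PlantConfig()
    for strategy in ("position", "hybrid", "cascade"):
        outs = []
        for _ in range(2):
            ctrl = make_controller(default_cfg.controllers[strategy],
                                   muscles, pc)
            seq = []
            for k in range(20):
                out = ctrl.step(sample(t=k * pc.loop_period, fe=5.0),
                                np.array([4.0, 0.1]), np.full(6, 20.0))
                seq.append(out.actuator_cmd.copy())
            outs.append(np.array(seq))
        np.testing.assert_array_equal(outs[0], outs[1])


# -------------------------------------------------------- Ziegler-Nichols

def test_ultimate_gain_matches_eigenvalue_oracle():
    """P-only control of a discretized second-order plant: the probing
    routine recovers the ultimate gain and period found independently by
    bisection on the closed-loop spectral radius."""
    I, b, dt = 2e-3, 0.02, 0.005
    # exact ZOH discretization of 1/(I s^2 + b s)
    a = b / I
    Ad = np.array([[1.0, (1 - math.exp(-a * dt)) / a],
                   [0.0, math.exp(-a * dt)]])
    Bd = np.array([(dt - (1 - math.exp(-a * dt)) / a) / b,
                   (1 - math.exp(-a * dt)) / b])
    C = np.array([1.0, 0.0])

    def spectral_radius(kp):
        return np.max(np.abs(np.linalg.eigvals(Ad - kp * np.outer(Bd, C))))

    lo, hi = 1e-3, 1e3
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        if spectral_radius(mid) < 1.0:
            lo = mid
        else:
            hi = mid
    ku_oracle = math.sqrt(lo * hi)
    eig = np.linalg.eigvals(Ad - ku_oracle * np.outer(Bd, C))
    w = abs(np.angle(eig[np.argmax(np.abs(eig))])) / dt
    tu_oracle = 2 * math.pi / w

    def run(kp):
        x = np.zeros(2)
        n = 600
        ys, ts = np.empty(n), np.empty(n)
        r = 1.0
        for k in range(n):
            u = kp * (r - C @ x)
            x = Ad @ x + Bd * u
            ys[k], ts[k] = C @ x, (k + 1) * dt
        return ts, ys

    cfg = ZNSearchConfig(kp_min=1e-3, step_deg=1.0, n_bisect=20)
    ku, tu = find_ultimate_gain(run, cfg, y_scale=1.0)
    assert ku == pytest.approx(ku_oracle, rel=0.05)
    assert tu == pytest.approx(tu_oracle, rel=0.05)


def test_no_ultimate_gain_raises():
    """A pure first-order lag never oscillates under P control."""
    def run(kp):
        y = 0.0
        dt = 0.01
        ys, ts = np.empty(200), np.empty(200)
        for k in range(200):
            y += dt * (-y + kp * (1.0 - y))
            ys[k], ts[k] = y, (k + 1) * dt
        return ts, ys

    with pytest.raises(RuntimeError):
        find_ultimate_gain(run, ZNSearchConfig(kp_max=4.0), y_scale=1.0)
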