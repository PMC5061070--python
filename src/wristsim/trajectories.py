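"""Desired wrist trajectories for the evaluation protocol.

Presets (ISB signs: flexion and ulnar deviation positive):

- ``FE30``: planar flexion-extension, amplitude 30 deg.
- ``RUD10``: planar radioulnar deviation, amplitude 10 deg.
- ``DTM``: dart thrower's motion — FE and RUD in phase, from 30 deg
  extension with 10 deg radial deviation to 30 deg flexion with 10 deg
  ulnar deviation (a straight line in the RUD-FE plane).
- ``CCD_CW`` / ``CCD_ACW``: circumduction — FE amplitude 20 deg and RUD
  amplitude 10 deg in quadrature (an ellipse). Clockwise visits flexion ->
  ulnar -> extension -> radial; anticlockwise visits flexion -> radial ->
  extension -> ulnar.

All presets are sinusoidal with a configurable cycle period (default 4 s)
and analytic accelerations for feedforward use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

MOTIONS = ("FE30", "RUD10", "DTM", "CCD_CW", "CCD_ACW", "CUSTOM")

#: Preset amplitudes (amp_fe, amp_rud) in degrees.
PRESET_AMPLITUDES = {
    "FE30": (30.0, 0.0),
    "RUD10": (0.0, 10.0),
    "DTM": (30.0, 10.0),
    "CCD_CW": (20.0, 10.0),
    "CCD_ACW": (20.0, 10.0),
}


@dataclass
class TrajectorySpec:
    motion: str = "FE30"
    amp_fe: float = 30.0     # deg
    amp_rud: float = 0.0     # deg
    period: float = 4.0      # s per cycle
    n_cycles: int = 3
    waveform: str = "sinusoid"

    def __post_init__(self) -> None:
        if self.motion not in MOTIONS:
            raise ValueError(f"unknown motion {self.motion!r}")
        if self.motion != "CUSTOM":
            self.amp_fe, self.amp_rud = PRESET_AMPLITUDES[self.motion]
        if not self.period > 0:
            raise ValueError("period must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.waveform != "sinusoid":
            raise ValueError("only sinusoidal waveforms are implemented")

    @property
    def duration(self) -> float:
        return self.period * self.n_cycles

    @property
    def moved_amplitude(self) -> float:
        """Amplitude of the principal (largest-amplitude) axis, deg."""
        return max(self.amp_fe, self.amp_rud)


@dataclass
class MotionSample:
    """One tick of the desired trajectory: angles (deg) and analytic
    angular accelerations (deg/s^2) for feedforward."""

    time: float
    theta_fe_d: float
    theta_rud_d: float
    accel_fe_d: float
    accel_rud_d: float


def _angles(spec: TrajectorySpec, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w = 2.0 * math.pi / spec.period
    s, c = np.sin(w * t), np.cos(w * t)
    if spec.motion in ("FE30", "RUD10", "DTM", "CUSTOM"):
        return spec.amp_fe * s, spec.amp_rud * s
    if spec.motion == "CCD_CW":
        # (20,0) flexion -> (0,10) ulnar -> (-20,0) extension -> (0,-10) radial
        return spec.amp_fe * c, spec.amp_rud * s
    # CCD_ACW: flexion -> radial -> extension -> ulnar
    return spec.amp_fe * c, -spec.amp_rud * s


def make_trajectory(spec: TrajectorySpec, loop_period: float,
                    joint_limits: np.ndarray | None = None) -> list[MotionSample]:
    """Sample the desired trajectory at the control rate.

    Accelerations are the analytic second derivatives of the sinusoids.
    ``joint_limits`` (2 x 2 deg, rows FE/RUD) rejects amplitudes the plant
    cannot reach.
    """
    if not loop_period > 0:
        raise ValueError("loop_period must be > 0")
    if loop_period > spec.period / 20:
        raise ValueError("loop_period must be <= trajectory period / 20")
    if joint_limits is not None:
        lim = np.asarray(joint_limits, float)
        for amp, (lo, hi) in zip((spec.amp_fe, spec.amp_rud), lim):
            if amp > min(hi, -lo):
                raise ValueError(f"amplitude {amp} deg exceeds joint limits")
    n = int(round(spec.duration / loop_period))
    t = np.arange(n) * loop_period
    fe, rud = _angles(spec, t)
    w2 = (2.0 * math.pi / spec.period) ** 2
    return [
        MotionSample(time=float(tk), theta_fe_d=float(f), theta_rud_d=float(r),
                     accel_fe_d=float(-w2 * f), accel_rud_d=float(-w2 * r))
        for tk, f, r in zip(t, fe, rud)
    ]
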