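import numpy as np
import pytest

import wristsim as ws
from wristsim.config import load_default_config
from wristsim.protocols import kinematic_error, run_simulation
from wristsim.trajectories import TrajectorySpec


@pytest.fixture(scope="session")
def muscles():
    return ws.default_muscles()


@pytest.fixture(scope="session")
def default_cfg():
    """Packaged default configuration with the frozen tuned gains."""
    return load_default_config()


@pytest.fixture(scope="session")
def planar_runs(default_cfg):
    """Closed-loop runs of the planar kinematic tests: position, hybrid and
    cascade control on FE-30 and RUD-10 in both hand orientations.

    Shared by the tracking-error, percent-error, cascade-constraint and
    completion checks so the 12 simulations run once per session.
    """
    runs = {}
    for strategy in ("position", "hybrid", "cascade"):
        cc = default_cfg.controllers[strategy]
        for motion in ("FE30", "RUD10"):
            spec = TrajectorySpec(motion=motion)
            for orientation in ("downward", "upward"):
                pc = ws.PlantConfig(orientation=orientation)
                res = run_simulation(pc, cc, spec, seed=1,
                                     muscles=default_cfg.muscles)
                rep = kinematic_error(res, spec) if res.completed else None
                runs[(strategy, motion, orientation)] = (res, rep)
    return runs


def random_muscle_set(rng: np.random.Generator) -> ws.MuscleSet:
    """A random 6-muscle geometry for solver stress tests (signs
    unconstrained; rank-2 guaranteed by rejection)."""
    while True:
        R = rng.uniform(-20.0, 20.0, (6, 2))
        pcsa = rng.uniform(0.5, 6.0, 6)
        try:
            return ws.MuscleSet(
                [ws.MuscleParams(n, p, rf, rr)
                 for n, p, (rf, rr) in zip(ws.MUSCLE_NAMES, pcsa, R)])
        except ValueError:
            continue
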