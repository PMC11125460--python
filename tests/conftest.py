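"""Shared fixtures: the default plant is expensive to compile into the
kernel once per session, so it is session-scoped."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

import balancesim as bs

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def model():
    return bs.build_default_model()


@pytest.fixture(scope="session")
def state0(model):
    return bs.initial_state(model)


@pytest.fixture(scope="session")
def passive_pendulum_model(model):
    """Muscle-free, contact-free variant with the floating base pinned:
    the legs swing about fixed hips as passive compound pendulums."""
    muscles = [replace(m, f_max=1e-12) for m in model.muscles]
    return model.with_changes(
        muscles=muscles, contact_spheres=[], joint_limits={},
        locked_coords=("pelvis_tx", "pelvis_ty", "pelvis_tilt"))


@pytest.fixture(scope="session")
def short_closed_loop(model):
    """One short closed-loop run with non-trivial gains (the packaged
    standing seed, which exercises all three feedback laws), reused by
    several cross-check tests."""
    from balancesim.optimize import default_initial_params
    params = default_initial_params(com_delay=0.1)
    traj = bs.simulate(model, params,
                       bs.PerturbationSpec(amplitude=0.01, duration=2.0))
    assert traj.n > 1000, "seed controller should survive the short run"
    return params, traj


def pendulum_energy(model, q9, qd9):
    """Total mechanical energy from the reference (Python) kinematics."""
    from balancesim.msk_model import body_frames, segment_com_positions
    st = bs.SimState(0.0, np.concatenate([[0.0], q9]),
                     np.concatenate([[0.0], qd9]), np.zeros(18))
    coms = segment_com_positions(model, st)
    frames = body_frames(model, st.q, st.qdot)
    ke = pe = 0.0
    for seg in model.segments:
        if seg.name == "platform":
            continue
        m, pos, vel = coms[seg.name]
        w = frames[seg.name][2]
        ke += 0.5 * m * float(vel @ vel) + 0.5 * seg.moment_of_inertia * w * w
        pe += m * model.gravity * pos[1]
    return ke + pe
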