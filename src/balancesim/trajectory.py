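"""Trajectory container and the closed-loop simulation entry point."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .control import ReflexParams, pack_controller
from .engine import ENGINE_COORDS, run_rollout
from .msk_model import PlanarModel, initial_state
from .perturbation import PerturbationSpec

MUSCLE_COLS = None  # filled lazily from the model


@dataclass
class Trajectory:
    """Time-indexed record of one simulation run.

    Arrays are sampled on the integration grid; ``t_term`` is the fall /
    end-of-run time and ``fell`` whether the run terminated early.
    """

    t: np.ndarray
    q: np.ndarray          # (n, 9) body coordinates, ENGINE_COORDS order
    qdot: np.ndarray
    act: np.ndarray        # (n, 18)
    exc: np.ndarray
    muscle_force: np.ndarray
    contact_normal: np.ndarray    # (n, 4)
    contact_tangential: np.ndarray
    com: np.ndarray        # (n, 2) AP, vertical
    com_vel: np.ndarray
    foot_com: np.ndarray   # (n, 2): AP position, AP velocity
    cop: np.ndarray        # (n,), NaN during flight
    platform: np.ndarray   # (n, 2): position, velocity
    grf: np.ndarray        # (n, 2): total tangential, total normal
    dt: float
    t_term: float
    fell: bool
    effort_integral: float
    dof_integral: float
    muscle_names: tuple[str, ...]
    condition_id: str = ""
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.t.shape[0]

    def column_frame(self) -> pd.DataFrame:
        """Flat tidy table of the full record (storage layout)."""
        data = {"time": self.t}
        for j, name in enumerate(ENGINE_COORDS):
            data[f"q_{name}"] = self.q[:, j]
        for j, name in enumerate(ENGINE_COORDS):
            data[f"qd_{name}"] = self.qdot[:, j]
        for j, name in enumerate(self.muscle_names):
            data[f"act_{name}"] = self.act[:, j]
        for j, name in enumerate(self.muscle_names):
            data[f"exc_{name}"] = self.exc[:, j]
        for j, name in enumerate(self.muscle_names):
            data[f"force_{name}"] = self.muscle_force[:, j]
        for j in range(self.contact_normal.shape[1]):
            data[f"contact_normal_{j}"] = self.contact_normal[:, j]
            data[f"contact_tangential_{j}"] = self.contact_tangential[:, j]
        data["com_x"] = self.com[:, 0]
        data["com_y"] = self.com[:, 1]
        data["com_vx"] = self.com_vel[:, 0]
        data["com_vy"] = self.com_vel[:, 1]
        data["foot_com_x"] = self.foot_com[:, 0]
        data["foot_com_vx"] = self.foot_com[:, 1]
        data["cop_x"] = self.cop
        data["platform_x"] = self.platform[:, 0]
        data["platform_vx"] = self.platform[:, 1]
        data["grf_x"] = self.grf[:, 0]
        data["grf_y"] = self.grf[:, 1]
        return pd.DataFrame(data)

    def meta(self) -> dict:
        return {"dt": self.dt, "t_term": self.t_term, "fell": self.fell,
                "effort_integral": self.effort_integral,
                "dof_integral": self.dof_integral,
                "condition_id": self.condition_id, "seed": self.seed}


def steady_initial_activations(model: PlanarModel, params: ReflexParams,
                               state0) -> np.ndarray:
    """Fixed point of the control loop at the resting start state.

    At t = 0 the fiber lengths and the COM offset are constant, so the
    commanded excitation is well defined up to the force-feedback term; a
    few fixed-point sweeps resolve that.  Starting activations there
    removes the non-physiological tone-onset transient of an all-silent
    start.
    """
    from .msk_model import muscle_reference_angles, whole_body_com
    from .muscle import force_length, force_passive, musculotendon_geometry
    from .engine import ENGINE_COORDS
    com, comv = whole_body_com(model, state0)
    fcom, fcomv = whole_body_com(model, state0, "feet-only")
    dp = fcom[0] - com[0]
    dv = fcomv[0] - comv[0]
    qref = muscle_reference_angles(model)
    q = dict(zip(ENGINE_COORDS, state0.q[1:]))
    l0_norm = np.array([musculotendon_geometry(m, q, None, qref).l_norm
                        for m in model.muscles])
    fl = np.array([force_length(l) for l in l0_norm])
    fp = np.array([force_passive(l) for l in l0_norm])
    KL = params.expand("K_L")
    L0 = params.expand("l_0")
    KCP = params.expand("K_CP")
    KCV = params.expand("K_CV")
    G = params.force_gain_matrix()
    a = np.zeros(18)
    for _ in range(8):
        f_norm = a * fl + fp    # v = 0
        u = KL * (l0_norm - L0) + G @ f_norm + KCP * dp + KCV * dv \
            + params.u_base
        a = np.clip(u, 0.0, 1.0)
    return a


def simulate(model: PlanarModel, params: ReflexParams | None,
             perturbation: PerturbationSpec = PerturbationSpec(),
             dt: float = 1e-3, state0=None, record: bool = True,
             excitations=None, fall_fraction: float = 0.9,
             steady_start: bool = True,
             condition_id: str = "", seed: int | None = None):
    """Run one closed-loop (or open-loop) simulation.

    With ``params`` given, the three-way feedback controller drives the
    muscles; with ``params=None``, the constant ``excitations`` array does
    (open loop).  ``steady_start`` initializes activations at the
    controller's resting fixed point instead of zero.  Returns a
    :class:`Trajectory` when recording, else just the scalar summary dict.
    """
    st = state0 if state0 is not None else initial_state(model)
    if params is not None and steady_start and np.all(st.act == 0):
        st = st.copy()
        st.act = steady_initial_activations(model, params, st)
    controller = pack_controller(model, params, dt) if params is not None else None
    rec, scalars = run_rollout(
        model, st.q[1:], st.qdot[1:], st.act, controller=controller,
        excitations=excitations, amplitude=perturbation.amplitude,
        frequency=perturbation.frequency, dt=dt,
        duration=perturbation.duration, fall_fraction=fall_fraction,
        record=record)
    if not record:
        return scalars
    n = scalars["rows"]
    names = tuple(m.name for m in model.muscles)
    return Trajectory(
        t=np.arange(n) * dt, q=rec["q"], qdot=rec["qd"], act=rec["act"],
        exc=rec["exc"], muscle_force=rec["F"], contact_normal=rec["cn"],
        contact_tangential=rec["ct"], com=rec["com"], com_vel=rec["comv"],
        foot_com=rec["fcom"], cop=rec["cop"], platform=rec["plat"],
        grf=rec["grf"], dt=dt, t_term=scalars["t_term"],
        fell=scalars["fell"], effort_integral=scalars["effort"],
        dof_integral=scalars["dof_integral"], muscle_names=names,
        condition_id=condition_id, seed=seed)


def joint_moment_series(model: PlanarModel, traj: Trajectory) -> pd.DataFrame:
    """Net muscle moments (N m, flexion-positive) per joint over time,
    summed across both legs for the hip, knee and ankle."""
    marm = model.packed().marm  # (18, 9)
    moments = traj.muscle_force @ marm  # (n, 9); cols 3..8 are the joints
    out = pd.DataFrame({"time": traj.t})
    cols = {name: i for i, name in enumerate(ENGINE_COORDS)}
    for joint in ("hip", "knee", "ankle"):
        out[joint] = (moments[:, cols[f"{joint}_r"]]
                      + moments[:, cols[f"{joint}_l"]])
    return out
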