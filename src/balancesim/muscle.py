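"""Hill-type muscle mechanics with a rigid tendon and constant moment arms.

Each leg carries nine muscle groups: gluteus maximus (GM), iliopsoas (IL),
hamstrings (HM), biceps femoris short head (BF), rectus femoris (RF), vasti
(VAS), gastrocnemius (GAS), soleus (SOL) and tibialis anterior (TA).  HM, RF
and GAS are biarticular.  Fiber length is an affine function of the joint
angles the muscle spans; the force law is the product of activation,
force-length, force-velocity and a passive-elastic term, scaled by the
maximal isometric force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

UNIQUE_MUSCLES = ("GM", "IL", "HM", "BF", "RF", "VAS", "GAS", "SOL", "TA")

TAU_ACT = 0.010    # s
TAU_DEACT = 0.040  # s

# force-curve shape constants
FL_WIDTH = 0.45          # Gaussian width of the active force-length curve
FV_ECC_MAX = 1.4         # eccentric plateau of the force-velocity curve
FV_ECC_C = 0.08          # eccentric curvature (slope-matched at v=0)
FV_CON_K = 0.25          # concentric curvature
FP_SHAPE = 4.0           # passive exponential shape factor
FP_STRAIN = 0.6          # fiber strain at which passive force reaches f_max
FP_CAP = 2.0             # passive force cap, units of f_max


@dataclass(frozen=True)
class MuscleSpec:
    """Parameters of one musculotendon actuator."""

    name: str
    f_max: float                       # N
    l_opt: float                       # m, optimal fiber length
    l_slack: float                     # m, tendon slack length (rigid tendon)
    v_max: float                       # optimal fiber lengths / s
    moment_arms: dict[str, float]      # joint coord -> m, flexion-positive
    reflex_delay: float                # s, t_Dm in [0.035, 0.100]

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.l_opt <= 0:
            raise ValueError(f"{self.name}: f_max and l_opt must be positive")
        if not (0.035 - 1e-12 <= self.reflex_delay <= 0.100 + 1e-12):
            raise ValueError(f"{self.name}: reflex delay outside [35, 100] ms")
        if len(self.moment_arms) < 1:
            raise ValueError(f"{self.name}: must span at least one joint")

    @property
    def base_name(self) -> str:
        return self.name.rsplit("_", 1)[0]


@dataclass(frozen=True)
class MuscleKinematics:
    """Normalized fiber length and velocity."""

    l_norm: float
    v_norm: float

    def __post_init__(self) -> None:
        if self.l_norm <= 0:
            raise ValueError("normalized fiber length must be positive")


def activation_step(u: float, a: float, dt: float,
                    tau_act: float = TAU_ACT, tau_deact: float = TAU_DEACT) -> float:
    """First-order excitation-to-activation dynamics, one explicit step.

    da/dt = (u - a)/tau with the fast time constant during excitation rise
    (u >= a) and the slow one during relaxation; the result is clamped to
    [0, 1].
    """
    tau = tau_act if u >= a else tau_deact
    a_new = a + dt * (u - a) / tau
    return min(1.0, max(0.0, a_new))


def musculotendon_geometry(spec: MuscleSpec, q: dict[str, float],
                           qdot: dict[str, float] | None = None,
                           q_ref: dict[str, float] | None = None) -> MuscleKinematics:
    """Fiber kinematics from joint angles via constant moment arms.

    The path length changes by ``-sum_j r_j * (theta_j - theta_ref_j)``;
    with a rigid tendon the fiber carries all of that change.  The reference
    posture (default: all spanned angles at their reference values of zero)
    is where the fiber sits at its optimal length.
    """
    qdot = qdot or {}
    q_ref = q_ref or {}
    dl = 0.0
    dv = 0.0
    for joint, r in spec.moment_arms.items():
        if joint not in q:
            raise ValueError(f"{spec.name} spans {joint} absent from q")
        dl -= r * (q[joint] - q_ref.get(joint, 0.0))
        dv -= r * qdot.get(joint, 0.0)
    fiber = spec.l_opt + dl
    if fiber <= 0:
        raise ValueError(f"{spec.name}: non-positive fiber length")
    return MuscleKinematics(l_norm=fiber / spec.l_opt,
                            v_norm=dv / (spec.l_opt * spec.v_max))


def force_length(l_norm: float) -> float:
    """Active force-length curve: Gaussian centred on the optimal length."""
    x = (l_norm - 1.0) / FL_WIDTH
    return math.exp(-x * x)


def force_velocity(v_norm: float) -> float:
    """Hill force-velocity curve.

    Unity at zero velocity, zero at the maximal shortening velocity
    (v_norm = -1), saturating eccentric branch with plateau ``FV_ECC_MAX``;
    the two branches are slope-matched at v = 0.
    """
    v = min(1.0, max(-1.0, v_norm))
    if v <= 0.0:
        return (1.0 + v) / (1.0 - v / FV_CON_K)
    return (FV_ECC_MAX * v + FV_ECC_C) / (v + FV_ECC_C)


def force_passive(l_norm: float) -> float:
    """Passive-elastic force, units of f_max.

    Standard exponential fiber elasticity: zero at and below the optimal
    length, reaching f_max at strain ``FP_STRAIN``, capped for numerical
    safety.  ``f_P = (exp(k (l-1)/e0) - 1) / (exp(k) - 1)``.
    """
    if l_norm <= 1.0:
        return 0.0
    f = (math.exp(FP_SHAPE * (l_norm - 1.0) / FP_STRAIN) - 1.0) \
        / (math.exp(FP_SHAPE) - 1.0)
    return min(FP_CAP, f)


def muscle_force(spec: MuscleSpec, a: float, kin: MuscleKinematics) -> float:
    """Tensile musculotendon force (N, >= 0)."""
    if not (0.0 <= a <= 1.0):
        raise ValueError("activation must lie in [0, 1]")
    f = spec.f_max * (a * force_length(kin.l_norm) * force_velocity(kin.v_norm)
                      + force_passive(kin.l_norm))
    return max(0.0, f)


def default_reflex_delays() -> np.ndarray:
    """Per-unique-muscle reflex delays (s) in UNIQUE_MUSCLES order."""
    from .msk_model import _load_defaults
    cfg = _load_defaults()
    return np.array([cfg["muscles"][m]["reflex_delay"] for m in UNIQUE_MUSCLES])
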