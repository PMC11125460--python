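"""The optimization objective: effort + fall penalty + DOF-range penalties.

``J = w_effort * ∫ Σ a_m² dt + w_fall (1 - t_term / t_end) + w_dof * J_dof``

with the integrals over [0, t_term].  The fall term punishes early
termination (COM height dropping below 0.9 of its initial value); J_dof
integrates indicator penalties for knee flexion beyond 30°, pelvis tilt
beyond ±15°, and pelvis AP translation beyond ±0.2 m from the start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ObjectiveWeights:
    w_effort: float = 1.0
    w_fall: float = 100.0
    w_dof: float = 1.0
    t_end: float = 10.0

    def __post_init__(self) -> None:
        if min(self.w_effort, self.w_fall, self.w_dof, self.t_end) < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class DOFLimits:
    knee_max_deg: float = 30.0
    pelvis_tilt_max_deg: float = 15.0
    pelvis_translation_max: float = 0.2   # m
    penalty_value: float = 10.0
    fall_fraction: float = 0.9

    def __post_init__(self) -> None:
        vals = (self.knee_max_deg, self.pelvis_tilt_max_deg,
                self.pelvis_translation_max, self.penalty_value,
                self.fall_fraction)
        if any(v <= 0 for v in vals):
            raise ValueError("limits must be positive")


def dof_penalty_rate(state, limits: DOFLimits = DOFLimits(),
                     initial_tx: float = 0.0) -> float:
    """Instantaneous J_dof integrand: sum of three indicator penalties.

    Accepts a SimState (10-coordinate) or a bare 9-entry engine coordinate
    vector.  Knee flexion beyond the limit on either leg, pelvis tilt beyond
    ±limit, and pelvis AP excursion beyond ±limit each contribute
    ``penalty_value``.
    """
    q = state.q if hasattr(state, "q") else np.asarray(state, dtype=float)
    if q.shape == (10,):
        q = q[1:]
    knee = max(q[4], q[7])
    pen = 0.0
    if knee > math.radians(limits.knee_max_deg):
        pen += limits.penalty_value
    if abs(q[2]) > math.radians(limits.pelvis_tilt_max_deg):
        pen += limits.penalty_value
    if abs(q[0] - initial_tx) > limits.pelvis_translation_max:
        pen += limits.penalty_value
    return pen


def check_termination(com_height: float, initial_com_height: float,
                      limits: DOFLimits = DOFLimits()) -> bool:
    """True iff the COM has fallen below ``fall_fraction`` of its initial
    height (strict inequality: exactly at the threshold is not a fall)."""
    if initial_com_height <= 0:
        raise ValueError("initial COM height must be positive")
    return com_height < limits.fall_fraction * initial_com_height


def evaluate_objective(traj, weights: ObjectiveWeights = ObjectiveWeights(),
                       limits: DOFLimits = DOFLimits()) -> float:
    """Objective value of a recorded trajectory.

    Effort and DOF-penalty integrals by trapezoid over the integration grid
    up to t_term; the fall term from the recorded termination time.
    """
    if traj.n == 0:
        raise ValueError("empty trajectory")
    sumsq = np.sum(traj.act ** 2, axis=1)
    effort = float(np.trapezoid(sumsq, dx=traj.dt))
    pen = np.zeros(traj.n)
    knee_lim = math.radians(limits.knee_max_deg)
    tilt_lim = math.radians(limits.pelvis_tilt_max_deg)
    knee = np.maximum(traj.q[:, 4], traj.q[:, 7])
    pen += limits.penalty_value * (knee > knee_lim)
    pen += limits.penalty_value * (np.abs(traj.q[:, 2]) > tilt_lim)
    pen += limits.penalty_value * (np.abs(traj.q[:, 0] - traj.q[0, 0])
                                   > limits.pelvis_translation_max)
    jdof = float(np.trapezoid(pen, dx=traj.dt))
    fall = weights.w_fall * (1.0 - traj.t_term / weights.t_end)
    return weights.w_effort * effort + fall + weights.w_dof * jdof
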