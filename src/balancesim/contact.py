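"""Foot-platform interaction: compliant normal contact, regularized friction,
and center-of-pressure extraction.

Normal forces follow a Hunt-Crossley law (Hertzian 3/2 exponent with
penetration-rate damping).  Friction is a single smooth velocity-regularized
law — no stick-state bookkeeping — whose regularization scale is the
transition velocity; it is zero at rest, peaks near the static coefficient
around the transition velocity, and tends to the dynamic-plus-viscous level
at large slip speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ContactSphere:
    segment: str                  # foot segment name
    local_offset: tuple[float, float]  # m, in the foot frame (ankle origin)
    radius: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class ContactParams:
    stiffness: float = 2.0e6          # N/m^2
    dissipation: float = 1.0          # s/m
    mu_static: float = 0.9
    mu_dynamic: float = 0.6
    mu_viscous: float = 0.6
    transition_velocity: float = 0.15  # m/s

    def __post_init__(self) -> None:
        vals = (self.stiffness, self.dissipation, self.mu_static,
                self.mu_dynamic, self.mu_viscous, self.transition_velocity)
        if any(v < 0 for v in vals):
            raise ValueError("contact parameters must be non-negative")
        if self.mu_static < self.mu_dynamic:
            raise ValueError("mu_static must be >= mu_dynamic")


@dataclass(frozen=True)
class ContactForce:
    point: tuple[float, float]  # world frame, m
    normal: float               # N, vertical, >= 0
    tangential: float           # N, anterior-posterior, signed

    def __post_init__(self) -> None:
        if self.normal < 0:
            raise ValueError("normal force must be non-negative")


def hunt_crossley_normal(depth: float, depth_rate: float,
                         params: ContactParams) -> float:
    """Normal force for a given penetration depth and rate.

    Zero out of contact; otherwise ``k * depth^1.5 * (1 + 1.5 * c * rate)``
    clamped at zero so rapid withdrawal never produces adhesion.
    """
    if depth <= 0.0:
        return 0.0
    f = params.stiffness * depth ** 1.5 * (1.0 + 1.5 * params.dissipation * depth_rate)
    return max(0.0, f)


def friction_coefficient(slip_speed: float, params: ContactParams) -> float:
    """Effective friction coefficient of the smooth regularized law.

    ``mu(s) = tanh(3 s) * (mu_d + (mu_s - mu_d) exp(-(s-1)^2)) + mu_v * v``
    with ``s = v / v_t``: continuous through zero, peak ~= mu_static near the
    transition velocity, asymptote ``mu_dynamic + mu_viscous * v``.
    """
    v = abs(slip_speed)
    s = v / params.transition_velocity
    stribeck = params.mu_dynamic + (params.mu_static - params.mu_dynamic) \
        * math.exp(-(s - 1.0) ** 2)
    return math.tanh(3.0 * s) * stribeck + params.mu_viscous * v


def friction_force(normal: float, slip_velocity: float,
                   params: ContactParams) -> float:
    """Signed tangential force opposing slip."""
    if normal < 0:
        raise ValueError("normal force must be non-negative")
    if normal == 0.0 or slip_velocity == 0.0:
        return 0.0
    mu = friction_coefficient(slip_velocity, params)
    return -math.copysign(mu * normal, slip_velocity)


def center_of_pressure(contacts: list[ContactForce]) -> float:
    """Normal-load-weighted AP application point of the contact forces.

    Raises ``FlightPhaseError`` when nothing carries load (no COP sample).
    """
    total = sum(c.normal for c in contacts)
    if total <= 0.0:
        raise FlightPhaseError("zero total normal load: no COP defined")
    return sum(c.normal * c.point[0] for c in contacts) / total


class FlightPhaseError(ValueError):
    """No foot-ground load; the COP signal has no sample here."""
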