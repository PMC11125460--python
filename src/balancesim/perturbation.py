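"""Sinusoidal platform drive, perturbation-phase taxonomy, and the
30-condition magnitude-by-delay experimental protocol.

The platform oscillates in the anterior-posterior direction at 1 Hz with
amplitude ("magnitude") 0-80 mm; each cycle splits into four quarter-cycle
phases by the signs of platform velocity and speed change: forward/backward
x accelerating/decelerating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class PhaseLabel(str, Enum):
    FA = "FA"  # forward, accelerating
    FD = "FD"  # forward, decelerating
    BA = "BA"  # backward, accelerating
    BD = "BD"  # backward, decelerating
    UNDEFINED = "undefined"  # zero-amplitude drive has no phase


@dataclass(frozen=True)
class PerturbationSpec:
    amplitude: float = 0.0   # m (half of peak-to-peak)
    frequency: float = 1.0   # Hz
    duration: float = 10.0   # s

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


@dataclass(frozen=True)
class Protocol:
    """The experimental grid: perturbation magnitudes x COM feedback delays."""

    magnitudes_mm: tuple[float, ...] = (0, 2, 4, 6, 8, 10, 20, 40, 60, 80)
    delays_ms: tuple[float, ...] = (100, 150, 200)
    frequency: float = 1.0
    duration: float = 10.0

    @property
    def n_conditions(self) -> int:
        return len(self.magnitudes_mm) * len(self.delays_ms)


@dataclass(frozen=True)
class Condition:
    delay_ms: float
    magnitude_mm: float

    @property
    def condition_id(self) -> str:
        return f"d{self.delay_ms:g}_m{self.magnitude_mm:g}"


def platform_position(spec: PerturbationSpec, t: float):
    """Platform position, velocity and acceleration at time t.

    ``x(t) = A sin(2 pi f t)``: the platform starts at zero moving forward.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    w = 2.0 * math.pi * spec.frequency
    return (spec.amplitude * math.sin(w * t),
            spec.amplitude * w * math.cos(w * t),
            -spec.amplitude * w * w * math.sin(w * t))


def phase_from_kinematics(v: float, a: float) -> PhaseLabel:
    """Quarter-cycle phase from instantaneous velocity and acceleration:
    forward/backward by the sign of v, accelerating/decelerating by the
    sign of v*a (speed change), independent of the drive's starting phase."""
    forward = v >= 0.0
    accelerating = v * a >= 0.0
    if forward:
        return PhaseLabel.FA if accelerating else PhaseLabel.FD
    return PhaseLabel.BA if accelerating else PhaseLabel.BD


def phase_label(spec: PerturbationSpec, t: float) -> PhaseLabel:
    """Perturbation phase of the sinusoidal drive at time t."""
    if spec.amplitude == 0.0:
        return PhaseLabel.UNDEFINED
    _, v, a = platform_position(spec, t)
    return phase_from_kinematics(v, a)


def enumerate_protocol(protocol: Protocol = Protocol()) -> list[Condition]:
    """Ordered condition list: by delay, then strictly ascending magnitude.

    Ascending magnitudes within each delay are required by the warm-started
    optimization sweep (each magnitude seeds the next).
    """
    out = []
    for d in protocol.delays_ms:
        for m in sorted(protocol.magnitudes_mm):
            out.append(Condition(delay_ms=d, magnitude_mm=m))
    return out
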