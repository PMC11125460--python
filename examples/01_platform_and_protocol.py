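"""The perturbation protocol: a sinusoidally translating platform.

Builds the 30-condition grid (10 magnitudes x 3 COM-feedback delays),
prints the drive's geometry at the largest magnitude, and labels the four
quarter-cycle phases.
"""

import numpy as np

from balancesim import (PerturbationSpec, Protocol, enumerate_protocol,
                        phase_label, platform_position)

protocol = Protocol()
conditions = enumerate_protocol(protocol)
print(f"protocol: {len(conditions)} conditions "
      f"({len(protocol.magnitudes_mm)} magnitudes x "
      f"{len(protocol.delays_ms)} delays)")
print("first five:", [c.condition_id for c in conditions[:5]])

spec = PerturbationSpec(amplitude=0.080, frequency=1.0)
ts = np.linspace(0.0, 1.0, 2001)
xs = np.array([platform_position(spec, t)[0] for t in ts])
vs = np.array([platform_position(spec, t)[1] for t in ts])
print(f"\n80 mm drive: peak-to-peak {1000 * (xs.max() - xs.min()):.1f} mm "
      f"per cycle, peak speed {vs.max():.3f} m/s")

print("\nphase at quarter-cycle midpoints:")
for t in (0.125, 0.375, 0.625, 0.875):
    print(f"  t = {t:.3f} s -> {phase_label(spec, t).value}")
# FD/BA/BD/FA: the sine drive launches at peak forward speed, so the first
# quarter is forward-decelerating.
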