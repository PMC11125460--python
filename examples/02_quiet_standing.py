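"""Quiet standing under closed-loop reflex + COM feedback control.

Simulates the packaged pre-tuned gain set on the static platform for 10 s
and prints the balance summary: the model should keep its COM above 90% of
the initial height throughout, with a small effort integral.
"""

import numpy as np

from balancesim import PerturbationSpec, build_default_model, simulate
from balancesim.optimize import default_initial_params

model = build_default_model()
params = default_initial_params(com_delay=0.100)
traj = simulate(model, params, PerturbationSpec(amplitude=0.0, duration=10.0))

print(f"stood for {traj.t_term:.1f} s (fell: {traj.fell})")
print(f"effort integral  sum a^2 dt : {traj.effort_integral:.2f}")
print(f"COM height range           : {traj.com[:, 1].min():.3f}"
      f" .. {traj.com[:, 1].max():.3f} m")
print(f"COM AP excursion           : "
      f"{1000 * (traj.com[:, 0].max() - traj.com[:, 0].min()):.1f} mm")
grf = traj.grf[-2000:, 1]
print(f"mean vertical load (last 2 s): {grf.mean():.0f} N "
      f"(body weight {model.body_mass * model.gravity:.0f} N)")
act = traj.act[-2000:]
busiest = np.argsort(act.mean(axis=0))[-3:][::-1]
names = [traj.muscle_names[i] for i in busiest]
print("most active muscles:",
      ", ".join(f"{n} ({act[:, i].mean():.2f})"
                for n, i in zip(names, busiest)))
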