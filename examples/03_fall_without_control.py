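"""Without feedback control the model falls.

Runs the uncontrolled model (baseline tone only, all gains zero) under the
largest 80 mm perturbation: the fall-termination rule fires when the COM
drops below 90% of its initial height, and the objective records the fall
penalty.
"""

from balancesim import (DOFLimits, ObjectiveWeights, PerturbationSpec,
                        ReflexParams, build_default_model, evaluate_objective,
                        simulate)

model = build_default_model()
zero_gains = ReflexParams(com_delay=0.100)   # all gains zero
traj = simulate(model, zero_gains,
                PerturbationSpec(amplitude=0.080, duration=10.0))

J = evaluate_objective(traj, ObjectiveWeights(), DOFLimits())
print(f"uncontrolled model at 80 mm: fell = {traj.fell}, "
      f"t_term = {traj.t_term:.3f} s")
print(f"objective J = {J:.2f} "
      f"(fall term alone: {100 * (1 - traj.t_term / 10):.2f})")
print(f"COM height: {traj.com[0, 1]:.3f} -> {traj.com[-1, 1]:.3f} m "
      f"(fall threshold {0.9 * traj.com[0, 1]:.3f} m)")
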