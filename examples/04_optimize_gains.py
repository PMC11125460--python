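"""Tuning controller gains with restarted CMA-ES.

Runs a small warm-started gain search for one perturbed condition (20 mm,
100 ms COM delay) and prints the per-restart objective values.  Desk-scale
budgets; the study-scale equivalent uses 60 restarts per condition and a
warm-started sweep over all 30 conditions (see ``balancesim sweep``).
"""

from balancesim import OptimizerConfig, build_default_model, optimize_condition
from balancesim.optimize import default_initial_params
from balancesim.perturbation import Condition

model = build_default_model()
cfg = OptimizerConfig(
    restarts=1, max_generations=40, seed=11, ftarget=None,
    warm_start=default_initial_params(0.100))
cond = Condition(delay_ms=100.0, magnitude_mm=20.0)

res = optimize_condition(model, cond, cfg)
print(f"condition {cond.condition_id}: best J = {res.best_J:.2f} "
      f"after {res.evaluations} simulations")
print(f"best controller stood {res.best_t_term:.1f} s "
      f"(fell: {res.best_fell})")
print("\noptimized gain summary (bilaterally shared):")
p = res.best_params
for i, name in enumerate(("GM", "IL", "HM", "BF", "RF", "VAS",
                          "GAS", "SOL", "TA")):
    print(f"  {name:>4}: K_L={p.K_L[i]:5.2f} l_0={p.l_0[i]:5.2f} "
          f"K_CP={p.K_CP[i]:+6.2f} K_CV={p.K_CV[i]:+6.2f}")
print(f"  K_F (pair gains): {[round(float(v), 2) for v in p.K_F]}")
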