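# Methods

`balancesim` is a predictive forward-dynamics study of perturbed standing
balance: nothing is fit to motion data.  A planar musculoskeletal model is
placed on a platform that translates sinusoidally in the anterior-posterior
(AP) direction; muscle excitations come entirely from three delayed
feedback laws whose gains are found by stochastic optimization against an
effort/fall/posture objective.  Everything below describes the model as it
is implemented, the parameters that matter, and the design decisions made
where the design was genuinely open.

## Plant

**Skeleton.** Sagittal-plane rigid-body tree: a fused pelvis+torso+head+arms
(HAT) segment on a 3-DOF floating base (AP translation, vertical
translation, forward tilt), plus bilateral thigh/shank/foot chains through
revolute hips, knees and ankles — 9 body DOFs.  Angle conventions are
physiological (hip/knee flexion positive, ankle dorsiflexion positive,
forward pelvis tilt positive); radians internally, degrees at I/O.

**Anthropometry.** Whole-body mass 74.5 kg and stature 1.8 m are fixed
totals; segment masses, lengths, COM offsets and radii of gyration follow
standard anthropometric regression fractions (Winter/de Leva style) scaled
to those totals.  All fractions live in `data/default_model.yaml`, not in
code.  Body-mass bookkeeping excludes the 10 kg platform, which is
kinematically prescribed (position-driven) rather than force-controlled:
prescribing the slider makes the perturbation exact and removes an
unidentified platform-controller gain.

**Joint stops.** Each hip/knee/ankle carries a passive range-of-motion stop
(a 300 N m/rad spring with 5 N m s/rad damping beyond the limit; knee
extension stop at 0°, hip −30..120°, ankle −50..40°).  The knee's extension
stop is load-bearing in near-straight standing, as in the skeleton and in
the gait-model family this plant is patterned on.  The stops are
dissipative by design and are disabled in the passive energy-conservation
tests, which probe the integrator, not the stops.

**Dynamics.** Joint-space equations of motion are evaluated in world-frame
planar spatial coordinates: composite-rigid-body algorithm for the mass
matrix, one recursive Newton-Euler pass (zero acceleration, gravity as a
base acceleration) for the velocity/gravity bias, and transposed point
Jacobians for contact wrenches.  Integration is fixed-step semi-implicit
(symplectic) Euler at dt = 1 ms.  A fixed step makes every delay an exact
multiple of dt, so the delay lines are exact; the integrator is first order
(verified by Richardson extrapolation) and conserves passive-swing energy
to < 0.1% per second at the default step.  Divergence (non-finite or
absurdly large state) is treated as a fall at that instant.

## Muscles

Eighteen Hill-type musculotendon actuators (nine per leg: GM, IL, HM, BF,
RF, VAS, GAS, SOL, TA; HM, RF and GAS biarticular) with rigid tendons and
constant moment arms.  Fiber length is therefore an affine function of the
spanned joint angles; the spec of each muscle (maximal isometric force,
optimal fiber length, moment arms, reflex latency) is configuration, drawn
from standard lower-limb literature values.

Force is `f_max · (a · f_L(l) · f_V(v) + f_P(l))` with

* `f_L(l) = exp(-((l-1)/0.45)^2)` — Gaussian active force-length curve;
* `f_V` — Hill hyperbola, zero at the maximal shortening velocity
  (v = −1 in optimal lengths/s, v_max = 10 l_opt/s), unity isometrically,
  eccentric plateau 1.4, slope-matched at v = 0;
* `f_P(l) = (exp(4(l-1)/0.6) - 1)/(exp(4) - 1)` — passive elasticity, zero
  at and below the optimal length, reaching f_max at 60% strain (capped at
  2).  A much stiffer passive curve was tried first and rejected: it made
  the plant passively quasi-rigid, so optimized controllers balanced with
  near-zero activation and the co-contraction analysis degenerated.

Excitation-to-activation dynamics are first order with τ_act = 10 ms and
τ_deact = 40 ms, clamped to [0, 1].

**Operating point.** Fibers are calibrated to sit at optimal length at a
reference posture of 35° hip/knee flexion and 20° dorsiflexion — deeper
than the working crouch.  In the working posture the anti-gravity extensors
therefore operate on the ascending limb of the force-length curve
(l_norm ≈ 0.88–0.92), where tonic activation contributes positive intrinsic
joint stiffness, as it does in vivo.  With the fibers instead calibrated at
the working posture itself, the force-length slope (and hence intrinsic
stiffness) is zero at rest, and the delayed feedback alone could not be
tuned to stand within any practical search budget.

## Contact

Toe and heel spheres (radius 3 cm) on each foot against the platform's flat
top surface.  Normal force is Hunt-Crossley,
`k · depth^{3/2} · (1 + 1.5 c ẋ)` with k = 2×10⁶ N/m², dissipation c = 1,
clamped at zero (no adhesion).  Friction is one smooth velocity-regularized
law — no stick-state bookkeeping —

`mu(s) = tanh(3s) · (mu_d + (mu_s - mu_d) e^{-(s-1)^2}) + mu_v·v`,
`s = |v|/v_t`,

with static/dynamic/viscous coefficients 0.9/0.6/0.6 and transition
velocity v_t = 0.15 m/s: zero at rest, peak ≈ mu_s near v_t, asymptote
mu_d + mu_v·v.  The regularization scale is v_t; the exact smooth form is
an implementation choice made for fixed-step stability.  The center of
pressure is the normal-load-weighted AP application point of the sphere
forces (no friction-moment correction); samples with zero total load are
flight-phase and carry no COP.

## Controller

Each muscle's excitation is the clipped sum of three laws plus a baseline
tone u_base = 0.01 (configurable to 0):

* **Stretch reflex** `u_L = K_L (l(t−t_Dm) − l_0)` on the muscle's own
  normalized fiber length.  Monosynaptic latencies t_Dm are assigned by
  anatomical distance: 35 ms (hip muscles), 60 ms (knee), 100 ms (ankle).
* **Antagonist force feedback** `u_F = K_F F̂(t−t_Dm)`, with F̂ the
  antagonist's force normalized by its own f_max (normalization makes the
  gain bounds transferable across muscles); when several antagonists map to
  one muscle their normalized forces are summed.  The wiring is the three
  mutual agonist/antagonist groups (GM+HM ↔ IL; HM+BF ↔ RF+VAS;
  GAS+SOL ↔ TA), one gain per direction (6 gains).
* **COM feedback**
  `u_COM = K_CP (p_foot − p_com)(t−t_D) + K_CV (ṗ_foot − ṗ_com)(t−t_D)`
  on the AP offset between the feet COM and the whole-body COM.  The COM
  delay t_D is the experimental variable: 100/150/200 ms for healthy,
  aging, and severely delayed sensing.  The scalar COM error is routed to
  the muscles through per-muscle signed gains (a global gain with a
  hand-made routing map is a special case of this).

Parameters are shared bilaterally, which halves the search dimension.  The
genome is 42 numbers: per unique muscle K_L ∈ [0,10], l_0 ∈ [0.5,1.5],
K_CP, K_CV ∈ [−20,20]; per directed pair K_F ∈ [0,5].  Delay lines return
the t = 0 signal for t < delay (the model starts at rest, so this is the
steady pre-perturbation value), and simulations start with activations at
the controller's resting fixed point rather than zero, which removes a
non-physiological tone-onset kick.

## Objective and optimization

`J = w_effort ∫ Σ a² dt + w_fall (1 − t_term/t_end) + w_dof J_dof` with
w_effort = w_dof = 1, w_fall = 100, t_end = 10 s.  A run terminates as a
fall when the COM height drops below 0.9 of its initial value (strict
inequality).  J_dof integrates indicator penalties of 10 for knee flexion
beyond 30° (either leg), pelvis tilt beyond ±15°, and pelvis AP excursion
beyond ±0.2 m.  Integrals are trapezoidal on the integration grid; the
compiled kernel accumulates them online and agrees with the trajectory-level
evaluation to round-off.

Gains are tuned by restarted CMA-ES (authored in-package: standard
(μ/μ_w, λ) strategy with rank-one/rank-μ covariance updates and cumulative
step-size adaptation; box constraints by repair-plus-quadratic-penalty;
validated against analytic minima).  The search runs in box-normalized
coordinates with initial step 0.2 (0.1 around a warm start), population
4 + ⌊3 ln n⌋ = 15.  The desk-scale protocol runs each condition in two
phases: a stability search (≤ 8 restarts of ≤ 150 generations, stopping at
the first non-falling solution below a loose objective ceiling of 50)
followed by an effort refinement (one 200-generation run at step 0.05
around the stable winner, no early stop), so delay conditions are compared
at matched optimization pressure.  The study-scale setting (60 restarts,
no early stop) is one config switch (`--full-scale`).  Within each delay
the magnitudes are optimized in ascending order, each warm-started from
the previous winner.

Because every silent or mistuned controller falls within a second, the
landscape around the origin is a broad fall plateau.  All searches are
therefore seeded from a packaged pre-tuned quiet-standing gain set
(`data/initial_reflex_params.txt`), produced by this package's own
optimizer and polished against a small delay × magnitude grid — the same
practice as the init-parameter files shipped with predictive-simulation
tools.  The seed is deliberately condition-specific: it falls under
perturbation and at longer delays, so per-condition optimization remains
real work.  The fully naive starting point is kept as
`neutral_initial_params`.

## Analysis

The first 2 s of each 10 s run are discarded (settling transient); the
remaining 8 s are segmented into one-second cycles, giving an 8 × n
ensemble per signal with per-sample mean and SD.

* **Co-contraction.** Rudolph's index
  `CCI = (Act_L/Act_H)(Act_L + Act_H)` (0/0 defined as 0) on the
  ensemble-mean activation curves of the five analysis pairs (VAS-HM,
  RF-HM, IL-HM, TA-GAS, TA-SOL), left/right averaged before pairing;
  the scalar per condition is the trapezoidal integral over one mean cycle
  (the cycle, not the full 8 s — the units of published integrals are not
  stated, and the mean-cycle reading is the one that matches Eq-level
  curves).
* **Balance strategy.** Net muscle moments at hip, knee and ankle (summed
  across legs) are cycle-segmented; at each within-cycle sample the Pearson
  correlation is computed **across the 8 cycles** for hip↔knee and
  ankle↔knee, which is the only reading that yields a per-time-step
  coefficient from per-cycle curves.  Signs classify the sample:
  (+,+) ankle, (+,−) knee, (−,+) hip, (−,−) mixed; |ρ| < 0.05 (or
  zero-variance samples) are non-significant.  Dominant strategy per
  condition is the largest time fraction over significant samples, with
  exact ties kept as sets; percentage tables normalize over significant
  samples.
* **Stability.** Per-sample COP − COM (AP), flight samples excluded with a
  count, summarized by the per-condition mean.
* **Statistics.** Two-sided paired t-tests across the magnitude grid
  (n = 10 pairs, df = 9) comparing delay conditions, α = 0.05; peak
  activations are peaks of the ensemble-mean curve.

Packaged reference CSVs carry the published benchmark's dominant-strategy
grid and CCI integrals for the 30-condition protocol; they feed the
analysis-operation tests (e.g., the 94% ankle-dominance arithmetic below
20 mm) and are never read by the simulator.

## What the desk-scale runs do and do not show

The shipped budgets reproduce the method, not the published numbers: the
original study ran 60 CMA-ES restarts per condition on a commercial
high-speed engine with unpublished muscle parameters.  Desk-scale runs
(seeded, ≈ minutes per condition on one CPU) demonstrate that (i) the
uncontrolled model falls and the optimizer produces non-falling controllers
at 0–20 mm, and (ii) the qualitative delay effect — more effort and higher
co-contraction needed at 200 ms than at 100 ms — emerges at the largest
magnitude both delays can hold.  Exact CCI values, strategy percentages and
p-values depend on the unpublished model details and the much larger search
budget, and are not reproduction targets here.  The synthetic protocol has
no sensor noise, no anticipation, no stepping, and a deterministic plant,
so passing tests say nothing about those aspects of real balance data.

## Numerical choices

dt = 1 ms (5 ms hard cap); delays rounded to integer steps; activations and
excitations clamped to [0, 1]; muscle force clamped ≥ 0; fiber length
floored at 0.05 l_opt inside the kernel; passive force capped at 2 f_max;
COP undefined (NaN) in flight; fall threshold strict (<); exact dominance
ties reported as tie sets; zero-variance correlations excluded as
non-significant; all randomness flows from explicit integer seeds through
named child seeds (restart seeds < 2³¹), and identical configuration +
seed reproduces every artifact bit-for-bit.
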