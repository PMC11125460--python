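# Default plant parameters for the planar standing-balance model.
#
# The published totals fix only whole-body mass (74.5 kg), stature (1.8 m),
# platform mass (10 kg) and the contact table; segment-level inertials follow
# standard anthropometric regression fractions (Winter/de Leva style) scaled
# to those totals, and muscle-level parameters are standard lower-limb
# literature values for the nine modelled muscle groups per leg.

gravity: 9.80665
total_mass: 74.5     # kg, body only (platform excluded)
height: 1.8          # m
platform_mass: 10.0  # kg, kinematically prescribed slider

# Fractions: mass of total body mass; length/rog of stature-scaled segment
# length; com measured from the proximal joint along the segment axis.
segments:
  hat:   {mass_frac: 0.678,  length_frac: 0.470, com_frac: 0.400, rog_frac: 0.496}
  thigh: {mass_frac: 0.100,  length_frac: 0.245, com_frac: 0.433, rog_frac: 0.323}
  shank: {mass_frac: 0.0465, length_frac: 0.246, com_frac: 0.433, rog_frac: 0.302}
  foot:  {mass_frac: 0.0145, length_frac: 0.152, com_frac: 0.500, rog_frac: 0.475}

foot_geometry:
  ankle_height_frac: 0.039   # sole-to-ankle height as fraction of stature
  heel_back_frac: 0.0375     # ankle-to-heel horizontal distance, fraction of stature
  sphere_radius: 0.03        # m, toe and heel contact spheres

contact:
  stiffness: 2.0e+6          # N/m^2
  dissipation: 1.0           # s/m
  mu_static: 0.9
  mu_dynamic: 0.6
  mu_viscous: 0.6
  transition_velocity: 0.15  # m/s

# Moment arms in m, constant, flexion-positive (ankle: dorsiflexion-positive).
# reflex_delay is the monosynaptic loop latency t_Dm in s, assigned by
# anatomical distance (hip 35 ms, knee 60 ms, ankle 100 ms).
muscles:
  GM:  {f_max: 1500.0, l_opt: 0.14, reflex_delay: 0.035, moment_arms: {hip: -0.062}}
  IL:  {f_max: 1500.0, l_opt: 0.10, reflex_delay: 0.035, moment_arms: {hip:  0.050}}
  HM:  {f_max: 3000.0, l_opt: 0.11, reflex_delay: 0.060, moment_arms: {hip: -0.060, knee:  0.030}}
  BF:  {f_max: 800.0,  l_opt: 0.11, reflex_delay: 0.060, moment_arms: {knee:  0.030}}
  RF:  {f_max: 1200.0, l_opt: 0.08, reflex_delay: 0.060, moment_arms: {hip:  0.049, knee: -0.042}}
  VAS: {f_max: 3500.0, l_opt: 0.09, reflex_delay: 0.060, moment_arms: {knee: -0.042}}
  GAS: {f_max: 2500.0, l_opt: 0.06, reflex_delay: 0.100, moment_arms: {knee:  0.020, ankle: -0.048}}
  SOL: {f_max: 4000.0, l_opt: 0.08, reflex_delay: 0.100, moment_arms: {ankle: -0.052}}
  TA:  {f_max: 900.0,  l_opt: 0.06, reflex_delay: 0.100, moment_arms: {ankle:  0.040}}

# Joint angles (deg, flexion/dorsiflexion-positive) at which each fiber sits
# exactly at its optimal length.  Chosen deeper than the working crouch so
# that anti-gravity extensors operate on the ascending limb of the
# force-length curve near standing, where tonic activation contributes
# positive intrinsic joint stiffness (as in vivo).
muscle_reference_posture:
  hip: 35.0
  knee: 35.0
  ankle: 20.0

# Passive range-of-motion stops (coordinate limit torques): a stiff linear
# spring with damping engages beyond each physiological limit.  The knee's
# 0-degree extension stop is what straight-leg standing rests on.
joint_limits:
  hip: [-30.0, 120.0]     # flexion, deg
  knee: [0.0, 140.0]      # flexion, deg (no hyperextension)
  ankle: [-50.0, 40.0]    # dorsiflexion, deg
  stiffness: 300.0        # N m / rad beyond the limit
  damping: 5.0            # N m s / rad beyond the limit

muscle_dynamics:
  tau_act: 0.010    # s, excitation->activation rise
  tau_deact: 0.040  # s, fall
  v_max: 10.0       # optimal fiber lengths per second
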