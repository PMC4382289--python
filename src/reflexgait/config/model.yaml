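# Planar 7-segment walker, 80 kg / 1.88 m nominal.
#
# Segment inertial values are reconstructions from the Geyer-Herr planar
# modeling tradition (anthropometric tables scaled so the total mass is
# 80 kg); they are editable here. Lengths in m, masses in kg, inertia about
# the segment COM in kg m^2. com_offset is expressed in the segment frame
# (origin at the proximal joint; trunk origin at the hip).
name: planar-walker-80kg
gravity: [0.0, -9.80665]
segments:
  trunk: {mass: 53.5, length: 0.8, com_offset: [0.0, 0.35], inertia_zz: 3.0}
  thigh: {mass: 8.5, length: 0.5, com_offset: [0.0, -0.3], inertia_zz: 0.15}
  shank: {mass: 3.5, length: 0.5, com_offset: [0.0, -0.3], inertia_zz: 0.05}
  foot:  {mass: 1.25, length: 0.2, com_offset: [0.05, -0.05], inertia_zz: 0.005}
# One-sided spring-damper joint stops engaging beyond the limit angle.
# Constants are reconstructions (not printed in the primary source).
joints:
  hip:   {limits_deg: [-30.0, 120.0], stiffness: 300.0, damping: 20.0}
  knee:  {limits_deg: [0.0, 150.0], stiffness: 300.0, damping: 10.0}
  ankle: {limits_deg: [-45.0, 40.0], stiffness: 300.0, damping: 2.0}
# The ankle joint center is raised above the sole; the two contact spheres
# sit at the heel and ball of the foot (foot-frame coordinates, m).
foot_geometry:
  heel_offset: [-0.06, -0.06]
  ball_offset: [0.14, -0.06]
contact:
  stiffness: 9.4281e5       # k, N m^-1.5
  dissipation: 2.0          # c, (m/s)^-1
  mu_static: 0.8
  mu_dynamic: 0.8
  mu_viscous: 0.5           # viscous friction coefficient, scaled by slip speed
  transition_speed: 0.1     # v_t, m/s
  sphere_radius: 0.01       # m
  contact_on_threshold: 20.0    # N; controller-level foot contact trigger
  contact_off_threshold: 5.0    # N; release hysteresis
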