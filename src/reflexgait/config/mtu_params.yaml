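# Hill-type musculotendon parameter table, one entry per muscle (per leg).
#
# Values are reconstructions in the Geyer-style planar-walker tradition;
# the RF (rectus femoris) row is an assumption — the planar reflex-walker
# literature this table descends from does not include RF.
#
# F_max N; l_opt m; v_max in l_opt/s; tendon_slack m; tau_act s;
# u0 = baseline excitation (dimensionless).
# Moment arms: r0 m; shape 'constant' (r = r0) or 'cosine'
# (r = r0 cos(c (q - qc))); dir = +1 if shortening drives the joint in the
# positive (flexion / dorsiflexion) direction. Path length is the exact
# integral of the moment arm, so virtual-work consistency holds by
# construction and is verified by tests.
muscles:
  ILPSO:
    F_max: 2000.0
    l_opt: 0.11
    v_max: 12.0
    tendon_slack: 0.10
    tau_act: 0.01
    u0: 0.01
    joints:
      - {joint: hip, dir: 1, shape: constant, r0: 0.08}
  GMAX:
    F_max: 1500.0
    l_opt: 0.11
    v_max: 12.0
    tendon_slack: 0.13
    tau_act: 0.01
    u0: 0.01
    joints:
      - {joint: hip, dir: -1, shape: constant, r0: 0.08}
  HAMS:
    F_max: 3000.0
    l_opt: 0.10
    v_max: 12.0
    tendon_slack: 0.31
    tau_act: 0.01
    u0: 0.01
    joints:
      - {joint: hip, dir: -1, shape: constant, r0: 0.06}
      - {joint: knee, dir: 1, shape: constant, r0: 0.04}
  RF:
    F_max: 1200.0
    l_opt: 0.08
    v_max: 12.0
    tendon_slack: 0.35
    tau_act: 0.01
    u0: 0.01
    joints:
      - {joint: hip, dir: 1, shape: constant, r0: 0.04}
      - {joint: knee, dir: -1, shape: cosine, r0: 0.04, c: 0.7, qc: 0.8}
  VAS:
    F_max: 6000.0
    l_opt: 0.08
    v_max: 12.0
    tendon_slack: 0.23
    tau_act: 0.01
    u0: 0.01
    joints:
      - {joint: knee, dir: -1, shape: cosine, r0: 0.05, c: 0.7, qc: 0.8}
  GAS:
    F_max: 1500.0
    l_opt: 0.05
    v_max: 12.0
    tendon_slack: 0.40
    tau_act: 0.01
    u0: 0.01
    joints:
      - {joint: knee, dir: 1, shape: constant, r0: 0.04}
      - {joint: ankle, dir: -1, shape: cosine, r0: 0.05, c: 1.0, qc: -0.2}
  SOL:
    F_max: 4000.0
    l_opt: 0.04
    v_max: 6.0
    tendon_slack: 0.26
    tau_act: 0.01
    u0: 0.01
    joints:
      - {joint: ankle, dir: -1, shape: cosine, r0: 0.05, c: 1.0, qc: -0.2}
  TA:
    F_max: 800.0
    l_opt: 0.06
    v_max: 12.0
    tendon_slack: 0.24
    tau_act: 0.01
    u0: 0.01
    joints:
      - {joint: ankle, dir: 1, shape: cosine, r0: 0.04, c: 1.0, qc: 0.2}
# Shared Hill-curve shape constants (reconstructed):
curves:
  fl_width: 0.56          # force-length bell width (fraction of l_opt)
  fl_logmin: -2.9957      # ln(0.05): value of the bell at the width edge
  fv_shape: 5.0           # Hill shortening curvature K
  fv_ecc_max: 1.5         # eccentric force plateau N
  pe_strain: 0.7          # fiber strain scale of the passive element
  tendon_strain: 0.04     # tendon strain at F_max
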