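# Reflex-controller wiring table.
#
# Each entry attaches one feedback law to one muscle in one gait mode
# (stance / early_swing / late_swing). Law parameters listed with bounds are
# free variables exposed to the optimizer, in file order; shared PD targets
# and the early->late swing trigger distance d_swing follow. Together with
# the 18 initial conditions this yields the 74-entry design vector (the
# count is asserted at startup). Both legs share one parameter set (the
# controller is left/right symmetric).
#
# Law types:
#   force     u = G * F_norm(t - D)                    (muscle's own force)
#   stretch   u = G * [l_norm(t - D) - H]+             (muscle's own fiber)
#   suppress  u = -G * F_norm_source(t - D)            (inhibition)
#   pd        u = [sign * (Kp (th(t-D) - th_des) + Kd thdot(t-D))]+
#             feature: trunk_lean (forward lean of the trunk), hip, knee
#             trunk_lean PD output is gated by the (delayed) fraction of
#             body support borne by the leg, so the two legs' balance
#             laws do not fight each other during double support
#   knee_guard u = -K * [guard_angle - q_knee]+ while the knee extends
#             (prevents stance knee hyperextension snap)
#   constant  u = C                                    (per-mode stim offset)
#
# Sensory delays are fixed, not optimized.
delays_ms: {ILPSO: 5, GMAX: 5, HAMS: 5, RF: 5, VAS: 10, GAS: 20, SOL: 20, TA: 20}
knee_guard_angle: 0.25    # rad knee flexion below which the guard engages

laws:
  # ----- stance: body support and trunk balance
  - {muscle: SOL, mode: stance, type: force, G: {bounds: [0.0, 5.0], init: 1.1}}
  - {muscle: GAS, mode: stance, type: force, G: {bounds: [0.0, 5.0], init: 1.1}}
  - {muscle: VAS, mode: stance, type: force, G: {bounds: [0.0, 5.0], init: 1.0}}
  - {muscle: VAS, mode: stance, type: knee_guard, K: {bounds: [0.0, 10.0], init: 2.0}}
  - {muscle: TA, mode: stance, type: stretch,
     G: {bounds: [0.0, 5.0], init: 1.1}, H: {bounds: [0.4, 1.3], init: 0.72}}
  - {muscle: TA, mode: stance, type: suppress, source: SOL,
     G: {bounds: [0.0, 3.0], init: 0.35}}
  - {muscle: GMAX, mode: stance, type: pd, feature: trunk_lean, sign: 1,
     target: theta_trunk,
     Kp: {bounds: [0.0, 20.0], init: 2.0}, Kd: {bounds: [0.0, 3.0], init: 0.3}}
  - {muscle: ILPSO, mode: stance, type: pd, feature: trunk_lean, sign: -1,
     target: theta_trunk,
     Kp: {bounds: [0.0, 20.0], init: 2.0}, Kd: {bounds: [0.0, 3.0], init: 0.3}}
  - {muscle: HAMS, mode: stance, type: pd, feature: trunk_lean, sign: 1,
     target: theta_trunk,
     Kp: {bounds: [0.0, 20.0], init: 1.0}, Kd: {bounds: [0.0, 3.0], init: 0.15}}
  - {muscle: SOL, mode: stance, type: constant, C: {bounds: [0.0, 0.5], init: 0.0}}
  - {muscle: GAS, mode: stance, type: constant, C: {bounds: [0.0, 0.5], init: 0.0}}
  - {muscle: VAS, mode: stance, type: constant, C: {bounds: [0.0, 0.5], init: 0.08}}
  - {muscle: GMAX, mode: stance, type: constant, C: {bounds: [0.0, 0.5], init: 0.05}}
  # swing initiation: hip-flexor stim builds as the trailing leg unloads
  - {muscle: ILPSO, mode: stance, type: constant, gate: unload,
     C: {bounds: [0.0, 0.6], init: 0.3}}
  - {muscle: HAMS, mode: stance, type: constant, C: {bounds: [0.0, 0.5], init: 0.02}}
  - {muscle: RF, mode: stance, type: constant, gate: unload,
     C: {bounds: [0.0, 0.5], init: 0.1}}
  - {muscle: TA, mode: stance, type: constant, C: {bounds: [0.0, 0.5], init: 0.01}}
  # ----- early swing: leg flexion and ground clearance
  - {muscle: ILPSO, mode: early_swing, type: stretch,
     G: {bounds: [0.0, 8.0], init: 2.0}, H: {bounds: [0.4, 1.3], init: 0.85}}
  - {muscle: HAMS, mode: early_swing, type: force, G: {bounds: [0.0, 5.0], init: 0.4}}
  - {muscle: RF, mode: early_swing, type: stretch,
     G: {bounds: [0.0, 8.0], init: 0.4}, H: {bounds: [0.4, 1.3], init: 0.9}}
  - {muscle: TA, mode: early_swing, type: stretch,
     G: {bounds: [0.0, 5.0], init: 1.1}, H: {bounds: [0.4, 1.3], init: 0.72}}
  - {muscle: ILPSO, mode: early_swing, type: constant, C: {bounds: [0.0, 0.6], init: 0.25}}
  - {muscle: HAMS, mode: early_swing, type: constant, C: {bounds: [0.0, 0.5], init: 0.0}}
  - {muscle: RF, mode: early_swing, type: constant, C: {bounds: [0.0, 0.5], init: 0.02}}
  - {muscle: TA, mode: early_swing, type: constant, C: {bounds: [0.0, 0.5], init: 0.05}}
  - {muscle: GAS, mode: early_swing, type: constant, C: {bounds: [0.0, 0.5], init: 0.0}}
  - {muscle: VAS, mode: early_swing, type: constant, C: {bounds: [0.0, 0.5], init: 0.0}}
  - {muscle: GMAX, mode: early_swing, type: constant, C: {bounds: [0.0, 0.5], init: 0.0}}
  # ----- late swing: stance preparation (hip/knee PD, foot placement)
  - {muscle: ILPSO, mode: late_swing, type: pd, feature: hip, sign: -1,
     target: theta_hip,
     Kp: {bounds: [0.0, 10.0], init: 1.5}, Kd: {bounds: [0.0, 2.0], init: 0.2}}
  - {muscle: GMAX, mode: late_swing, type: pd, feature: hip, sign: 1,
     target: theta_hip,
     Kp: {bounds: [0.0, 10.0], init: 1.5}, Kd: {bounds: [0.0, 2.0], init: 0.2}}
  - {muscle: VAS, mode: late_swing, type: pd, feature: knee, sign: 1,
     target: theta_knee,
     Kp: {bounds: [0.0, 10.0], init: 1.0}, Kd: {bounds: [0.0, 2.0], init: 0.15}}
  - {muscle: HAMS, mode: late_swing, type: pd, feature: knee, sign: -1,
     target: theta_knee,
     Kp: {bounds: [0.0, 10.0], init: 0.6}, Kd: {bounds: [0.0, 2.0], init: 0.1}}
  - {muscle: HAMS, mode: late_swing, type: force, G: {bounds: [0.0, 5.0], init: 0.5}}
  - {muscle: TA, mode: late_swing, type: stretch,
     G: {bounds: [0.0, 5.0], init: 1.1}, H: {bounds: [0.4, 1.3], init: 0.72}}
  - {muscle: ILPSO, mode: late_swing, type: constant, C: {bounds: [0.0, 0.5], init: 0.01}}
  - {muscle: GMAX, mode: late_swing, type: constant, C: {bounds: [0.0, 0.5], init: 0.02}}
  - {muscle: VAS, mode: late_swing, type: constant, C: {bounds: [0.0, 0.5], init: 0.02}}
  - {muscle: HAMS, mode: late_swing, type: constant, C: {bounds: [0.0, 0.5], init: 0.02}}
  - {muscle: RF, mode: late_swing, type: constant, C: {bounds: [0.0, 0.5], init: 0.0}}
  - {muscle: TA, mode: late_swing, type: constant, C: {bounds: [0.0, 0.5], init: 0.05}}

# shared PD targets (rad): trunk forward lean, swing hip flexion,
# landing knee flexion
targets:
  theta_trunk: {bounds: [-0.1, 0.4], init: 0.10}
  theta_hip: {bounds: [0.0, 1.0], init: 0.40}
  theta_knee: {bounds: [0.0, 1.2], init: 0.25}

# early -> late swing trigger: ankle ahead of the COM by more than d_swing (m)
d_swing: {bounds: [0.0, 0.45], init: 0.18}
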