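# Methods

`reflexgait` synthesizes human walking by forward simulation of a planar
neuromusculoskeletal model under reflex control, optimizing the controller
rather than tracking recorded motion. This note documents the model, its
parameters, the numerical choices, and what the synthetic test fixtures do
and do not establish.

## Skeletal model

The skeleton is a sagittal-plane kinematic tree with 7 segments — a lumped
trunk/head/arms segment and thigh, shank and foot per leg — connected by
pin joints at the hips, knees and ankles. It has 9 degrees of freedom:
planar trunk position and pitch plus six joint angles,

    q = [trunk_x, trunk_y, trunk_pitch, hip_R, knee_R, ankle_R,
         hip_L, knee_L, ankle_L].

Sign convention: x forward, y up, angles right-handed about z; hip flexion,
knee flexion and ankle dorsiflexion are positive (the gait-figure
convention — the source literature does not fix signs). Dynamics use
minimal coordinates: pin joints are satisfied exactly and the equations of
motion are evaluated by a planar recursive Newton-Euler algorithm (mass
matrix by unit-acceleration passes, bias by a zero-acceleration pass),
verified against closed-form pendula, a symbolic Lagrangian oracle and
energy conservation.

Segment masses, lengths, COM offsets and inertias live in
`config/model.yaml`. The numeric values are reconstructions in the
Geyer-style planar-walker tradition, scaled so the whole body is 80 kg at
1.88 m stature (trunk 53.5 kg, thigh 8.5, shank 3.5, foot 1.25 kg per
side). The ankle joint center sits 0.07 m above the sole ("raised ankle"),
with contact spheres at the heel and ball of the foot. Joint limits are
one-sided spring-dampers (default 300 N·m/rad; damping 20/10/2 N·m·s/rad
for hip/knee/ankle) that engage only beyond the limit angle; the squared
limit torque integrates into the hyperextension penalty (HPE).

## Contact

Normal force at each 1-cm sphere follows the Hunt-Crossley law
`GRF_y = k h^1.5 (1 + 1.5 c h_dot)` with k = 9.4281e5 N·m^-1.5 and
c = 2 (m/s)^-1, clamped below at zero because the unclamped law produces
adhesion during fast retraction. Friction is `GRF_x = -mu(v) GRF_y` with a
piecewise-cubic Stribeck blend: a smooth stiction ramp reaching mu_s at the
transition speed v_t = 0.1 m/s, a blend down to mu_d by 3 v_t, plus a
viscous term mu_v |v| (mu_s = mu_d = 0.8, mu_v = 0.5 s/m — mu_v multiplies
slip speed, so it carries inverse-velocity units). The curve is
continuously differentiable and odd in slip velocity.

For controller triggering, a foot counts as "in contact" when its total
normal force exceeds 20 N, releasing below 5 N (hysteresis suppresses
chatter at touchdown).

## Musculotendon units

Eight Hill-type MTUs per leg (ILPSO, GMAX, HAMS, RF, VAS, GAS, SOL, TA;
HAMS, RF and GAS biarticular). Fiber force is
`F_max [ a f_L(l~) f_V(v~) + f_PE(l~) ]` with a cubic-exponential
force-length bell (width 0.56 l_opt), a Hill hyperbola for shortening and
a smooth saturating eccentric branch (plateau 1.5 F_max, C1 at zero
velocity), and a quadratic parallel elastic element above l_opt. The
series tendon is quadratic in strain with 4% strain at F_max. The fiber
length l_ce is a state: each step the tendon force follows from the series
stretch and the fiber velocity from inverting the force-velocity relation
(tendon-fiber force equilibrium); a rigid-tendon fallback is available.
The lengthening rate is capped at v_max — the inverse blows up near the
eccentric plateau and unbounded rates destabilize integration.

Moment arms are constants or cosine curves of the joint angle
(`config/mtu_params.yaml`); the MTU path length is the exact integral of
the moment arm, so virtual-work consistency holds by construction and is
asserted in tests. All MTU parameters are reconstructions; the RF row is
an assumption (the planar reflex-walker literature the table descends from
has no RF), flagged in the config.

Activation follows first-order dynamics (tau = 10 ms) integrated with the
exact exponential update, so activations stay in [0, 1] for any step. A
fixed baseline excitation u0 = 0.01 keeps activations strictly positive.

## Reflex controller

Excitation of each muscle is a clipped sum of a baseline, per-mode
constant offsets, and feedback laws on sensory signals delayed by fixed
propagation times: 5 ms (ILPSO/GMAX/HAMS/RF), 10 ms (VAS), 20 ms
(GAS/SOL/TA). Laws: force feedback `G_F F~(t-D)`, stretch feedback
`G_L [l~(t-D) - H]+`, rectified PD on angular features
`[K_p (theta - theta_des) + K_d theta_dot]+`, inhibition by another
muscle's force, and a knee-overextension guard on VAS.

A per-leg three-mode machine (stance, early swing, late swing) selects the
active laws: contact gain puts the leg in stance, contact loss in early
swing, and early swing hands over to late swing ("stance preparation")
when the ankle moves more than d_SWING ahead of the COM. Stance implements
trunk-balance PD on the hip muscles and hamstrings — gated by the
(delayed) fraction of total vertical GRF the leg bears, so the two legs'
balance laws share the task smoothly through double support — plus
positive force feedback of the plantarflexors and VAS; early swing is stretch-driven hip
flexion with hamstring braking; late swing adds hip and knee PD for the
landing configuration. The exact wiring is declarative data in
`config/controller.yaml` — deviations from it are visible and testable —
and enumerates 55 free law parameters plus the shared PD targets. With
d_SWING and 18 initial conditions (9 coordinates, 9 velocities) the design
vector has 74 entries, asserted at startup. Both legs share one parameter
set (left/right symmetric control).

The published count reads "56 MTU controller parameters and d_SWING ...
along with 18 initial conditions" against a printed total of 74; since
56 + 1 + 18 = 75, this package resolves the ambiguity by counting d_SWING
inside the 56.

The stance trunk-PD target is measured as trunk lean from vertical in the
simulation frame; on inclines (realized by rotating gravity, see below)
this equals lean from the slope normal. A lean-from-gravity-vertical
convention would require only a constant target shift.

## Metabolic energy

Whole-body metabolic power is basal rate plus per-muscle
activation/maintenance heat, shortening heat and positive fiber work — the
classic heat-rate structure. Per-muscle rates scale with estimated muscle
mass `m = F_max l_opt rho / sigma` (density 1059.7 kg/m^3, specific
tension 0.25 MPa). Defaults: activation/maintenance 74 W per kg muscle at
full activation, shortening heat 0.25 x shortening power, lengthening
contributes no heat, basal 1.2 W per kg body (unloaded mass), giving level
walking costs in the physiologically plausible few-W/kg range. All
coefficients are editable; the model object is pluggable so an alternative
energetics formulation can be swapped in.

## Objective

    R = w_fail J_fail + w_vel J_vel + w_head J_head + w_effort J_effort,
    w = (500000, 50, 25, 1)

- `J_fail = (1/T_fall)(T_total - T_fall)`, zero if the vertical COM never
  drops below 0.7 m. On inclines the COM height is measured normal to the
  slope plane (the simulation frame's y), the configurable convention.
- `J_vel`: deadband penalty `Q(v - 1.5, 0.05)` on step-averaged forward
  COM speed at each heel-strike, where a step spans consecutive
  heel-strikes of alternating feet (sub-0.1 s contact chatter is
  debounced). Two hardening rules close degenerate optima that the
  optimizer otherwise finds: a rollout that completes no step without
  falling (a stable stander) is penalized on its whole-rollout mean
  forward speed, and whenever the interval from the last heel-strike to
  the rollout end exceeds 0.8 s (stepping ceased — e.g. gliding on
  planted feet after one early speed-matched pseudo-step), a virtual
  end-of-rollout event is appended whose trailing-interval mean speed is
  penalized. Honest periodic gaits are unaffected.
- `J_head`: deadband penalty (epsilon = 0.2 m/s) on the forward velocity
  of the trunk top relative to the COM, sampled at 100 Hz.
- `J_effort`: mean of metabolic power plus 0.005 x HPE, normalized by
  total (body + load) mass.

## Scenarios

Backpack load is a point mass `M_back = f M_body` fixed 0.1 m posterior to
the trunk COM with own inertia 0.15 M_back kg·m^2, folded into the trunk
as a composite body. Inclines rotate the gravity vector while the contact
plane stays at y = 0 — dynamically equivalent to tilting the ground
(verified to 1e-8 on a passive-block trajectory) — so reported kinematics
live in the slope frame and forward speed is measured along the slope.
Scenario optimizations warm-start from the previous scenario's solution
(continuation), as load or incline increases.

## Numerics

Semi-implicit Euler at a fixed 0.1 ms step. The step divides the 5/10/20
ms delays and the 100 Hz objective sampling exactly, so delayed lookups
are exact ring-buffer reads and rollouts are bitwise deterministic. The
step is 5x finer than the delay granularity requires because the
Hunt-Crossley dissipation term acts as a stiff configuration-dependent
damper (up to ~15 kN·s/m at impact penetrations) on the 1.25 kg foot;
at coarser steps the explicit damping force is unstable. Non-finite
states truncate the rollout, which is then scored as a fall.

CMA-ES runs in bound-normalized coordinates with sigma0 = 0.15 of the
range by default; candidates are clipped into bounds before evaluation
(simple and reproducible). The start point is always evaluated so a warm
start is never lost to an unlucky first generation. Within a generation,
evaluations are independent; parallel results are re-ordered by candidate
index before selection, making parallel and serial runs identical.

## Synthetic fixtures and what tests show

`gait_analysis.generate_fixtures` produces deterministic reference bands
(smooth low-order Fourier curves with SD envelopes), synthetic EMG
(Gaussian baseline with inserted bursts at known onset times), and exactly
periodic trajectories. These exercise every analysis operation — band
coverage, Teager-Kaiser onset detection, stride averaging — against known
ground truth. They emulate the *format and structure* of experimental
gait data, not its content: passing these tests establishes correctness of
the analysis pipeline, not agreement of simulated gait with human data.
Assessing that agreement requires real reference bands supplied as CSV.

The packaged warm start (`config/warm_start.json`) was produced by CMA-ES
on the level, unloaded scenario with 5-s rollouts and a desk-scale budget
(hundreds of iterations at population 16, single host), not the
cluster-scale budget (~2000 iterations, 48 nodes, 10-s rollouts) that full
gait-quality claims would require. The closed-loop smoke test therefore
validates that the whole loop — dynamics, muscles, reflexes, objective,
optimizer — produces a stable, roughly speed-matched gait; it does not
claim publication-grade kinematic fidelity.

## Known limitations

- 2D: no coronal/transverse motion, no separate arm dynamics.
- Reflex wiring is one defensible instantiation of the stance/swing
  feedback scheme; other wirings with the same parameter count exist.
- The energetics coefficients are reconstructions; absolute W/kg values
  should be read as calibrated estimates, with the basal rate the main
  tuning constant.
- Joint-stop constants and moment-arm curves are plausible
  reconstructions, not fits to the uncited source tables.
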