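# reflexgait

Predictive simulation of human walking: a planar muscle-driven skeletal
model controlled by delayed reflex laws, whose control parameters and
initial conditions are optimized to produce emergent gaits — on level
ground, carrying backpack loads, and up inclines — without tracking any
recorded motion.

The package is aimed at biomechanics and motor-control researchers who
want a fully inspectable, deterministic reimplementation of the
reflex-controlled walking paradigm: every model table (segment inertias,
musculotendon parameters, controller wiring) is editable config, every
rollout is bitwise reproducible, and the optimizer is a self-contained
CMA-ES.

## The model in brief

- **Skeleton** — 7 segments (trunk/head/arms lump, thighs, shanks, feet),
  9 sagittal-plane DOFs, 80 kg / 1.88 m, minimal-coordinate dynamics via a
  planar recursive Newton-Euler algorithm.
- **Muscles** — 8 Hill-type musculotendon units per leg (ILPSO, GMAX,
  HAMS, RF, VAS, GAS, SOL, TA) with force-length-velocity fiber mechanics,
  elastic tendons, and first-order activation dynamics.
- **Contact** — Hunt-Crossley spheres at heel and ball of each foot,
  `GRF_y = k h^1.5 (1 + 1.5 c h_dot)`, with smooth Stribeck friction.
- **Control** — per-muscle force feedback `u = G_F F(t-D)`, stretch
  feedback `u = G_L [l(t-D) - H]+`, and rectified PD laws, switched by a
  per-leg stance / early-swing / late-swing mode machine; sensory delays
  fixed at 5/10/20 ms by muscle group.
- **Objective** — `R = w_fail J_fail + w_vel J_vel + w_head J_head +
  w_effort J_effort` with weights (500000, 50, 25, 1): don't fall (COM
  above 0.7 m), walk at 1.5 m/s (0.05 m/s deadband), keep the head steady
  (0.2 m/s deadband), and minimize metabolic power plus a small
  joint-limit (hyperextension) penalty.
- **Optimization** — the 74-entry design vector (56 controller parameters
  including the swing trigger distance d_SWING, plus 18 initial
  conditions) is searched with CMA-ES; loaded and inclined scenarios
  warm-start from the previous solution (continuation).

See `docs/methods.md` for the full account, including every numerical
choice and known limitation.

## Worked example

Run a 5-second closed-loop rollout from the packaged warm-start controller
and score it:

```python
import numpy as np
from reflexgait.optimizer import DesignVector, RolloutObjective
from reflexgait.simulation import Scenario, rollout
from reflexgait.objective import total_objective, step_speeds
from reflexgait.warm_start import load_warm_start

scenario = Scenario(duration=5.0)          # level, unloaded, 1.5 m/s target
obj = RolloutObjective(scenario)
model, muscles, codec = obj._setup()
cp, ic = codec.decode(load_warm_start().vector)
traj = rollout(model, cp, ic, scenario=scenario, muscles=muscles)

print("fell:", traj.fell)
print("strides (R):", len(traj.heel_strikes("r")) - 1)
print("mean step speed: %.2f m/s" % np.mean(step_speeds(traj)[1]))
rep = total_objective(traj)
print("R = %.3f  (J_fail=%.3g, J_vel=%.3g, J_head=%.3g, J_effort=%.3g)"
      % (rep["R"], rep["J_fail"], rep["J_vel"], rep["J_head"],
         rep["J_effort"]))
```

which prints (for the packaged warm start):

```
fell: False
strides (R): 19
mean step speed: 1.46 m/s
R = 34.510  (J_fail=0, J_vel=0.547, J_head=0.058, J_effort=5.73)
```

`J_fail = 0` means the vertical COM never dropped below 0.7 m over the
whole rollout; the mean step speed sits inside the 1.45-1.55 m/s target
deadband. The packaged controller comes from a desk-scale optimization
budget: the gait is stable and speed-matched but walks with a higher
cadence and metabolic cost (`J_effort`, W/kg of total mass) than a
converged cluster-scale solution would; longer CMA-ES runs (see
`reflexgait optimize`) continue to lower R.

From the shell, the same rollout is:

```sh
reflexgait simulate --out rollout.sto      # writes .sto, .csv and events
reflexgait optimize --seed 1 --max-iter 50 # refine the controller
reflexgait analyze rollout.csv --report report.json
```

Scenario files are small YAML documents, e.g. `{load_fraction: 0.2}` for a
20%-bodyweight backpack or `{incline_deg: 10}` for a 10-degree slope.

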