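"""The four-term rollout cost R = w_fail J_fail + w_vel J_vel + w_head J_head
+ w_effort J_effort.

J_fail punishes early falls (vertical COM below 0.7 m), J_vel penalizes
step-averaged forward COM speed outside a deadband around the target,
J_head penalizes forward head motion relative to the COM (visual/vestibular
stabilization), and J_effort is the mass-normalized mean of metabolic power
plus a small squared joint-limit-torque (hyperextension) penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .simulation import Trajectory

log = logging.getLogger(__name__)

# a trailing heel-strike-free interval longer than this means stepping has
# ceased (normal steps last ~0.5-0.6 s)
TAIL_STEP_S = 0.8


@dataclass(frozen=True)
class ObjectiveWeights:
    w_fail: float = 500000.0
    w_vel: float = 50.0
    w_head: float = 25.0
    w_effort: float = 1.0
    target_speed: float = 1.5   # m/s along the slope
    vel_epsilon: float = 0.05   # m/s deadband half-width
    head_epsilon: float = 0.2   # m/s
    hpe_coeff: float = 0.005
    fall_height: float = 0.7    # m


def q_penalty(d: float, eps: float) -> float:
    """Deadband quadratic: d^2 when |d| > eps, else 0."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    return d * d if abs(d) > eps else 0.0


def j_fail(trajectory: Trajectory,
           fall_height: float = 0.7) -> float:
    """(1 / T_fall) (T_total - T_fall); zero when the model never fell.

    ``fall_height`` documents the convention; the fall event itself is
    detected during the rollout with the same threshold.
    """
    if not trajectory.fell:
        return 0.0
    T = trajectory.duration
    t_fall = max(trajectory.t_fall, 1e-9)
    return (1.0 / t_fall) * (T - t_fall)


def step_speeds(trajectory: Trajectory):
    """Step-averaged forward COM speed at each heel-strike.

    A step spans consecutive heel-strikes of either leg; the speed at a
    heel-strike time is the mean forward COM velocity over the preceding
    step. Returns (times, speeds).
    """
    hs = np.sort(np.concatenate([trajectory.heel_strikes("r"),
                                 trajectory.heel_strikes("l")]))
    if len(hs) < 2:
        return np.array([]), np.array([])
    fr_t = trajectory.extras["fr_t"]
    fr_x = trajectory.extras["fr_comx"]
    x = np.interp(hs, fr_t, fr_x)
    dt_steps = np.diff(hs)
    # debounce: contact chatter can register sub-0.1 s "steps" that carry
    # no meaningful step-averaged velocity
    good = dt_steps > 0.1
    return hs[1:][good], np.diff(x)[good] / dt_steps[good]


def j_vel(trajectory: Trajectory, target_speed: float = 1.5,
          eps: float = 0.05) -> float:
    """Mean deadband penalty on step-averaged forward speed at heel-strikes.

    With no complete steps the term is 0 for a fallen rollout (the fall
    term dominates there), but a rollout that stops stepping *without*
    falling — standing, or gliding on planted feet — must not escape the
    velocity requirement: whenever the interval from the last heel-strike
    to the end of the rollout exceeds ``TAIL_STEP_S`` (much longer than a
    walking step), a virtual end-of-rollout event is appended whose
    "previous step" is that trailing interval.
    """
    ts, speeds = step_speeds(trajectory)
    penalties = [q_penalty(v - target_speed, eps) for v in speeds]
    if not trajectory.fell:
        fr_t = trajectory.extras["fr_t"]
        fr_x = trajectory.extras["fr_comx"]
        hs = np.concatenate([trajectory.heel_strikes("r"),
                             trajectory.heel_strikes("l"), [fr_t[0]]])
        t_last = float(np.max(hs))
        tail = fr_t[-1] - t_last
        if tail > TAIL_STEP_S:
            x_last = float(np.interp(t_last, fr_t, fr_x))
            vbar = (fr_x[-1] - x_last) / tail
            penalties.append(q_penalty(vbar - target_speed, eps))
    if not penalties:
        log.warning("j_vel: fallen rollout without complete steps; 0")
        return 0.0
    return float(np.mean(penalties))


def j_head(trajectory: Trajectory, eps: float = 0.2) -> float:
    """Mean deadband penalty on head-relative-to-COM forward velocity
    over the 100 Hz sample set."""
    hv = trajectory.head_vel
    return float(np.mean([q_penalty(v, eps) for v in hv]))


def j_effort(trajectory: Trajectory, hpe_coeff: float = 0.005) -> float:
    """Mass-normalized mean of metabolic power plus the weighted
    hyperextension penalty, W/kg of total (body + load) mass."""
    m_tot = trajectory.body_mass + trajectory.back_mass
    integrand = trajectory.metabolic_power + hpe_coeff * trajectory.hpe
    return float(np.mean(integrand) / m_tot)


def total_objective(trajectory: Trajectory,
                    weights: ObjectiveWeights | None = None) -> dict:
    """Weighted sum R with a per-term breakdown."""
    w = weights if weights is not None else ObjectiveWeights()
    terms = {
        "J_fail": j_fail(trajectory, w.fall_height),
        "J_vel": j_vel(trajectory, w.target_speed, w.vel_epsilon),
        "J_head": j_head(trajectory, w.head_epsilon),
        "J_effort": j_effort(trajectory, w.hpe_coeff),
    }
    R = (w.w_fail * terms["J_fail"] + w.w_vel * terms["J_vel"]
         + w.w_head * terms["J_head"] + w.w_effort * terms["J_effort"])
    return {"R": R, **terms,
            "weights": {"w_fail": w.w_fail, "w_vel": w.w_vel,
                        "w_head": w.w_head, "w_effort": w.w_effort}}
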