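"""Objective terms: deadband algebra, fall penalty, velocity/head/effort
terms and the weighted total."""

import numpy as np
import pytest

from reflexgait.objective import (ObjectiveWeights, j_effort, j_fail, j_head,
                                  j_vel, q_penalty, step_speeds,
                                  total_objective)
from tests.conftest import make_trajectory


class TestQPenalty:
    def test_inside_deadband_is_free(self):
        assert q_penalty(0.03, 0.05) == 0.0
        assert q_penalty(-0.05, 0.05) == 0.0

    def test_quadratic_outside(self):
        assert q_penalty(0.06, 0.05) == pytest.approx(0.0036)
        assert q_penalty(-0.2, 0.05) == pytest.approx(0.04)

    def test_negative_eps_rejected(self):
        with pytest.raises(ValueError):
            q_penalty(0.1, -1.0)


class TestJFail:
    def test_no_fall_is_zero(self):
        traj = make_trajectory(duration=10.0, fell=False)
        assert j_fail(traj) == 0.0

    def test_fall_at_five_seconds(self):
        traj = make_trajectory(duration=10.0, fell=True, t_fall=5.0)
        assert j_fail(traj) == pytest.approx(1.0)

    def test_fall_at_nine_seconds(self):
        traj = make_trajectory(duration=10.0, fell=True, t_fall=9.0)
        assert j_fail(traj) == pytest.approx(1.0 / 9.0)

    def test_later_falls_cost_less(self):
        costs = [j_fail(make_trajectory(duration=10.0, fell=True, t_fall=tf))
                 for tf in (2.0, 5.0, 8.0)]
        assert costs[0] > costs[1] > costs[2]


class TestJVel:
    def _traj_with_steps(self, speeds, step_time=0.6):
        """Alternating-leg heel strikes with prescribed per-step mean
        forward speed (COM track built by integration)."""
        n_steps = len(speeds)
        hs = np.arange(n_steps + 1) * step_time
        duration = hs[-1] + 0.5
        traj = make_trajectory(duration=duration, com_speed=0.0)
        fr_t = traj.extras["fr_t"]
        # exact piecewise-linear COM track: slope between consecutive heel
        # strikes equals the prescribed step-mean speed
        x_anchor = np.concatenate([[0.0],
                                   np.cumsum(np.array(speeds) * step_time)])
        traj.extras["fr_comx"] = np.interp(fr_t, hs, x_anchor)
        traj.extras["heel_strikes"]["r"] = hs[::2]
        traj.extras["heel_strikes"]["l"] = hs[1::2]
        return traj

    def test_exact_target_speed_is_free(self):
        traj = self._traj_with_steps([1.5, 1.5, 1.5])
        assert j_vel(traj, 1.5, 0.05) == 0.0

    def test_speed_inside_deadband_is_free(self):
        traj = self._traj_with_steps([1.47, 1.47, 1.47])
        assert j_vel(traj, 1.5, 0.05) == 0.0

    def test_two_steps_one_fast(self):
        traj = self._traj_with_steps([1.60, 1.50])
        assert j_vel(traj, 1.5, 0.05) == pytest.approx(0.005, rel=1e-6)

    def test_no_steps_fallen_rollout_returns_zero(self):
        traj = make_trajectory(duration=2.0, fell=True, t_fall=1.0)
        assert j_vel(traj, 1.5, 0.05) == 0.0

    def test_standing_still_without_steps_is_penalized(self):
        traj = make_trajectory(duration=2.0, com_speed=0.0)
        assert j_vel(traj, 1.5, 0.05) == pytest.approx(1.5 ** 2)

    def test_no_steps_but_drifting_at_target_speed_is_free(self):
        traj = make_trajectory(duration=2.0, com_speed=1.5)
        assert j_vel(traj, 1.5, 0.05) == 0.0

    def test_stopping_after_an_early_step_is_penalized(self):
        # one speed-matched step early on, then gliding to a halt: the
        # stalled tail must not evade the velocity requirement
        traj = make_trajectory(duration=5.0, com_speed=0.0)
        fr_t = traj.extras["fr_t"]
        x = np.where(fr_t < 0.3, 1.5 * fr_t, 1.5 * 0.3)
        traj.extras["fr_comx"] = x
        traj.extras["heel_strikes"]["r"] = np.array([0.05])
        traj.extras["heel_strikes"]["l"] = np.array([0.25])
        assert j_vel(traj, 1.5, 0.05) > 0.5

    def test_step_speeds_recovered(self):
        traj = self._traj_with_steps([1.2, 1.6, 1.4])
        _, sp = step_speeds(traj)
        assert np.allclose(sp, [1.2, 1.6, 1.4], atol=1e-6)


class TestJHead:
    def test_head_locked_to_com_is_free(self):
        traj = make_trajectory(head_vel=0.0)
        assert j_head(traj) == 0.0

    def test_constant_excess_head_velocity(self):
        traj = make_trajectory(head_vel=0.3)
        assert j_head(traj, 0.2) == pytest.approx(0.09)

    def test_within_deadband_is_free(self):
        traj = make_trajectory(head_vel=0.19)
        assert j_head(traj, 0.2) == 0.0


class TestJEffort:
    def test_constant_power_normalization(self):
        traj = make_trajectory(metabolic=80.0, hpe=0.0, body_mass=80.0)
        assert j_effort(traj) == pytest.approx(1.0)

    def test_hpe_increases_effort(self):
        lo = make_trajectory(metabolic=80.0, hpe=100.0)
        hi = make_trajectory(metabolic=80.0, hpe=200.0)
        assert j_effort(hi) > j_effort(lo)
        assert j_effort(lo) == pytest.approx(1.0 + 0.005 * 100.0 / 80.0)

    def test_load_normalizes_by_total_mass(self):
        unloaded = make_trajectory(metabolic=80.0, body_mass=80.0)
        loaded = make_trajectory(metabolic=80.0, body_mass=80.0,
                                 back_mass=16.0)
        assert j_effort(loaded) == pytest.approx(j_effort(unloaded) * 80.0
                                                 / 96.0)


class TestTotalObjective:
    def test_effort_only_with_default_weights(self):
        traj = make_trajectory(metabolic=80.0)
        rep = total_objective(traj)
        assert rep["R"] == pytest.approx(rep["J_effort"])
        assert rep["J_fail"] == 0.0

    def test_fall_dominates(self):
        traj = make_trajectory(fell=True, t_fall=5.0)
        rep = total_objective(traj)
        assert rep["R"] >= 500000.0

    def test_zero_weights_zero_cost(self):
        w = ObjectiveWeights(w_fail=0, w_vel=0, w_head=0, w_effort=0)
        traj = make_trajectory(fell=True, t_fall=3.0, metabolic=200.0,
                               head_vel=1.0)
        assert total_objective(traj, w)["R"] == 0.0

    def test_terms_nonnegative(self):
        traj = make_trajectory(fell=True, t_fall=2.0, metabolic=300.0,
                               head_vel=0.5, hpe=50.0)
        rep = total_objective(traj)
        for k in ("J_fail", "J_vel", "J_head", "J_effort"):
            assert rep[k] >= 0.0
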