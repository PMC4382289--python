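"""Reflex law algebra, delay exactness, parameter layout and the gait-mode
machine."""

import numpy as np
import pytest

from reflexgait.reflex_control import (ControlLayout, ControlParams,
                                       DelayBuffer, GaitMode,
                                       compose_excitation, force_feedback,
                                       muscle_excitation, pd_feedback,
                                       stretch_feedback, update_gait_mode)
from reflexgait.simulation import _excite_kernel
from reflexgait.mtu import MUSCLES


class TestLawAlgebra:
    def test_force_feedback_scalar(self):
        assert force_feedback(1.2, 0.5) == pytest.approx(0.6)
        assert force_feedback(1.2, 0.0) == 0.0

    def test_stretch_feedback_threshold(self):
        assert stretch_feedback(2.0, 1.0, 1.0) == 0.0
        assert stretch_feedback(2.0, 1.1, 1.0) == pytest.approx(0.2)
        assert stretch_feedback(2.0, 0.9, 1.0) == 0.0

    def test_pd_feedback_rectification(self):
        assert pd_feedback(10.0, 0.0, 0.1, 0.0, 0.0) == pytest.approx(1.0)
        assert pd_feedback(10.0, 0.0, 0.0, 0.0, 0.0) == 0.0
        assert pd_feedback(10.0, 1.0, -0.2, -0.1, 0.0) == 0.0

    def test_compose_baseline_and_saturation(self):
        assert compose_excitation(0.01, []) == pytest.approx(0.01)
        assert compose_excitation(0.01, [0.8, 0.9]) == 1.0
        assert compose_excitation(0.01, [-0.5]) == 0.0

    def test_stance_sol_composition(self):
        p = ControlParams.zeros()
        p.GF[6, 0] = 1.2       # SOL force feedback in stance
        u = muscle_excitation(p, 6, 0, F_del=0.5, l_del=0.0, theta_del=0.0,
                              thetadot_del=0.0, F_sup_del=0.0,
                              q_knee_del=0.5, qd_knee_del=0.0)
        assert u == pytest.approx(min(0.01 + 1.2 * 0.5, 1.0))


def test_kernel_and_reference_excitations_agree():
    """The jitted kernel matches the reference composition on random
    parameter/signal draws covering every law."""
    rng = np.random.default_rng(3)
    layout = ControlLayout.default()
    for _ in range(200):
        theta = rng.uniform(layout.lower, layout.upper)
        p = layout.decode(theta)
        m = rng.integers(0, 8)
        mode = rng.integers(0, 3)
        args = dict(F_del=rng.uniform(0, 1.5), l_del=rng.uniform(0.4, 1.6),
                    theta_del=rng.uniform(-1, 1),
                    thetadot_del=rng.uniform(-5, 5),
                    F_sup_del=rng.uniform(0, 1.5),
                    q_knee_del=rng.uniform(-0.2, 1.2),
                    qd_knee_del=rng.uniform(-5, 5),
                    load_share=rng.uniform(0, 1))
        ref = muscle_excitation(p, m, mode, **args)
        ker = _excite_kernel(p.u0[m], p.C[m], p.C_gate[m], p.GF[m], p.GL[m],
                             p.H[m], p.GS[m], p.sup_source[m], p.KP[m],
                             p.KD[m], p.theta_target[m], p.pd_feature[m],
                             p.pd_sign[m], p.KG[m], p.guard_angle, mode,
                             args["F_del"], args["l_del"], args["theta_del"],
                             args["thetadot_del"], args["F_sup_del"],
                             args["q_knee_del"], args["qd_knee_del"],
                             args["load_share"])
        assert ker == pytest.approx(ref, abs=1e-12)


def test_zero_gains_collapse_to_baseline():
    p = ControlParams.zeros()
    for m in range(8):
        for mode in range(3):
            u = muscle_excitation(p, m, mode, 0.7, 1.3, 0.5, 1.0, 0.4, 0.5,
                                  0.1)
            assert u == pytest.approx(p.u0[m])


class TestDelays:
    def test_delay_buffer_exact_lookup(self):
        buf = DelayBuffer(1, 40, initial=np.zeros(1))
        signal = np.sin(np.arange(200) * 0.1)
        for i, s in enumerate(signal):
            buf.push(np.array([s]))
            for d in (10, 20, 40):
                if i >= d:
                    assert buf.delayed(d)[0] == signal[i - d]

    def test_delay_cross_correlation_peak(self):
        """A probe through the buffer is shifted by exactly D for each
        muscle-group delay (5/10/20 ms at 0.1 ms steps)."""
        rng = np.random.default_rng(0)
        probe = rng.standard_normal(3000)
        buf = DelayBuffer(1, 200, initial=np.zeros(1))
        for d_ms, steps in ((5, 50), (10, 100), (20, 200)):
            out = np.zeros_like(probe)
            buf2 = DelayBuffer(1, 200, initial=np.zeros(1))
            for i, s in enumerate(probe):
                buf2.push(np.array([s]))
                out[i] = buf2.delayed(steps)[0]
            xc = np.correlate(out, probe, "full")
            lag = np.argmax(xc) - (len(probe) - 1)
            assert lag == steps

    def test_capacity_validation(self):
        buf = DelayBuffer(2, 10)
        with pytest.raises(ValueError):
            buf.delayed(11)

    def test_fixed_delay_assignment(self):
        layout = ControlLayout.default()
        d = dict(zip(MUSCLES, layout.delays_s))
        assert d["ILPSO"] == d["GMAX"] == d["HAMS"] == d["RF"] == 0.005
        assert d["VAS"] == 0.010
        assert d["GAS"] == d["SOL"] == d["TA"] == 0.020


class TestGaitModeMachine:
    def test_stance_to_early_swing_on_liftoff(self):
        m = update_gait_mode(GaitMode.STANCE, False, 0.0, 0.0, 0.15)
        assert m == GaitMode.EARLY_SWING

    def test_early_to_late_on_ankle_ahead_of_com(self):
        m = update_gait_mode(GaitMode.EARLY_SWING, False, 0.20, 0.0, 0.15)
        assert m == GaitMode.LATE_SWING
        m = update_gait_mode(GaitMode.EARLY_SWING, False, 0.10, 0.0, 0.15)
        assert m == GaitMode.EARLY_SWING

    def test_any_swing_to_stance_on_contact(self):
        assert update_gait_mode(GaitMode.LATE_SWING, True, 0.5, 0.0,
                                0.15) == GaitMode.STANCE
        assert update_gait_mode(GaitMode.EARLY_SWING, True, 0.0, 0.0,
                                0.15) == GaitMode.STANCE


class TestParameterLayout:
    def test_controller_exposes_56_free_parameters(self):
        assert ControlLayout.default().n_free == 56

    def test_decode_encode_round_trip(self):
        layout = ControlLayout.default()
        rng = np.random.default_rng(5)
        theta = rng.uniform(layout.lower, layout.upper)
        assert np.allclose(layout.encode(layout.decode(theta)), theta)

    def test_shared_targets_broadcast(self):
        layout = ControlLayout.default()
        theta = layout.init_vector
        p = layout.decode(theta)
        # trunk PD target shared by GMAX, ILPSO, HAMS in stance
        assert p.theta_target[1, 0] == p.theta_target[0, 0] \
            == p.theta_target[2, 0]

    def test_wrong_length_rejected(self):
        layout = ControlLayout.default()
        with pytest.raises(ValueError):
            layout.decode(np.zeros(10))

    def test_bounds_are_finite_and_ordered(self):
        layout = ControlLayout.default()
        assert np.all(layout.lower < layout.upper)
        assert np.all(np.isfinite(layout.lower))
        assert np.all(np.isfinite(layout.upper))
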