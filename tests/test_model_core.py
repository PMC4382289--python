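"""Rigid-body dynamics oracles: closed-form pendula, energy conservation,
symmetry, COM kinematics and joint-limit torques."""

import numpy as np
import pytest

from reflexgait import _engine
from reflexgait.model_core import (ModelState, SkeletonModel, build_tree,
                                   com_kinematics, forward_dynamics,
                                   joint_limit_torque, mechanical_energy)

G = 9.80665


def _walker_state():
    return ModelState(np.array([0.0, 1.0, 0.1, 0.3, 0.4, -0.2, 0.1, 0.2,
                                0.05]),
                      np.array([1.0, -0.2, 0.3, 0.5, -0.4, 0.2, -0.1, 0.3,
                                -0.2]))


def test_zero_gravity_equilibrium_has_zero_accelerations(model):
    st = ModelState(_walker_state().q, np.zeros(9))
    import dataclasses
    m0 = dataclasses.replace(model, gravity=np.zeros(2), _arrays=None)
    acc = forward_dynamics(m0, st, np.zeros(9))
    assert np.allclose(acc, 0.0, atol=1e-12)


@pytest.mark.parametrize("theta", [0.1, 0.4, 1.2, -0.7])
def test_single_pendulum_matches_closed_form(theta):
    m, d, I = 2.0, 0.3, 0.02
    tree = build_tree([dict(parent=-1, joint="pin", mass=m, inertia=I,
                            com=(0.0, -d))])
    qdd = _engine.forward_dynamics_core(*tree.full, np.array([theta]),
                                        np.zeros(1), np.zeros(1), 0.0, -G)
    I_pivot = I + m * d * d
    assert qdd[0] == pytest.approx(-(m * G * d / I_pivot) * np.sin(theta),
                                   rel=1e-12)


def test_double_pendulum_matches_lagrangian_oracle():
    """Independent symbolic (Lagrangian) derivation of a 2-link chain."""
    import sympy as sp

    m1, m2 = 2.0, 1.5
    L1 = 0.6
    d1, d2 = 0.3, 0.25
    I1, I2 = 0.03, 0.02

    q1, q2, w1, w2 = sp.symbols("q1 q2 w1 w2")
    # COM positions of both links (pendulum hanging toward -y)
    x1, y1 = d1 * sp.sin(q1), -d1 * sp.cos(q1)
    xj, yj = L1 * sp.sin(q1), -L1 * sp.cos(q1)
    x2 = xj + d2 * sp.sin(q1 + q2)
    y2 = yj - d2 * sp.cos(q1 + q2)
    vx1 = sp.diff(x1, q1) * w1
    vy1 = sp.diff(y1, q1) * w1
    vx2 = sp.diff(x2, q1) * w1 + sp.diff(x2, q2) * w2
    vy2 = sp.diff(y2, q1) * w1 + sp.diff(y2, q2) * w2
    T = (m1 * (vx1**2 + vy1**2) / 2 + I1 * w1**2 / 2
         + m2 * (vx2**2 + vy2**2) / 2 + I2 * (w1 + w2)**2 / 2)
    V = m1 * G * y1 + m2 * G * y2
    qs, ws = [q1, q2], [w1, w2]
    M = sp.Matrix(2, 2, lambda i, j: sp.diff(T, ws[i], ws[j]))
    # Euler-Lagrange bias: dt(dT/dw) - dT/dq + dV/dq at qdd = 0
    bias = sp.Matrix([
        sum(sp.diff(sp.diff(T, ws[i]), qs[k]) * ws[k] for k in range(2))
        - sp.diff(T, qs[i]) + sp.diff(V, qs[i]) for i in range(2)])
    sol = sp.lambdify((q1, q2, w1, w2),
                      (M.inv() * (-bias)).T, "numpy")

    tree = build_tree([
        dict(parent=-1, joint="pin", mass=m1, inertia=I1, com=(0.0, -d1)),
        dict(parent=0, joint="pin", mass=m2, inertia=I2, com=(0.0, -d2),
             anchor=(0.0, -L1)),
    ])
    rng = np.random.default_rng(0)
    for _ in range(10):
        q = rng.uniform(-1.5, 1.5, 2)
        w = rng.uniform(-3, 3, 2)
        qdd = _engine.forward_dynamics_core(*tree.full, q, w, np.zeros(2),
                                            0.0, -G)
        expect = np.asarray(sol(q[0], q[1], w[0], w[1])).ravel()
        assert np.allclose(qdd, expect, rtol=1e-6, atol=1e-9)


def test_passive_energy_conservation_over_one_second(model):
    st = _walker_state()
    arr = model.arrays()
    q, qd = st.q.copy(), st.qdot.copy()
    E0 = mechanical_energy(model, ModelState(q, qd))
    dt = 1e-4
    for _ in range(10000):
        qdd = _engine.forward_dynamics_core(*arr.full, q, qd, np.zeros(9),
                                            model.gravity[0],
                                            model.gravity[1])
        qd = qd + dt * qdd
        q = q + dt * qd
    E1 = mechanical_energy(model, ModelState(q, qd))
    assert abs(E1 - E0) < 2e-3 * abs(E0)


def test_left_right_mirror_symmetry(model):
    st = _walker_state()
    perm = [0, 1, 2, 6, 7, 8, 3, 4, 5]
    a = forward_dynamics(model, st, np.zeros(9))
    b = forward_dynamics(model, st.mirrored(), np.zeros(9))
    assert np.allclose(a, b[perm], rtol=0, atol=1e-10)


def test_singular_mass_matrix_raises():
    tree_model = SkeletonModel.default()
    import dataclasses
    bad = dataclasses.replace(tree_model, _arrays=None)
    arr = bad.arrays()
    arr.mass[3] = 0.0
    arr.inertia[3] = 0.0
    st = _walker_state()
    with pytest.raises(ValueError, match="singular"):
        forward_dynamics(bad, st, np.zeros(9))


class TestComKinematics:
    def test_stationary_model_has_zero_com_velocity(self, model):
        st = ModelState(_walker_state().q, np.zeros(9))
        _, v = com_kinematics(model, st)
        assert np.allclose(v, 0.0)

    def test_two_body_weighted_mean(self):
        tree = build_tree([
            dict(joint="free", mass=60.0, inertia=1.0, com=(0.0, 0.0)),
            dict(parent=0, joint="pin", mass=20.0, inertia=0.1,
                 com=(0.0, -0.5)),
        ])
        q = np.array([0.0, 1.0, 0.0, 0.0])   # masses at heights 1.0 and 0.5
        cx, cy, vx, vy, mtot = _engine.com_state(
            *tree.tree, tree.mass, tree.com_local, tree.dof0, q, np.zeros(4))
        assert cy == pytest.approx(0.875)
        assert mtot == pytest.approx(80.0)

    def test_rigid_translation_gives_com_velocity(self, model):
        st = ModelState(_walker_state().q, np.zeros(9))
        st.qdot[0], st.qdot[1] = 1.3, -0.4
        _, v = com_kinematics(model, st)
        assert np.allclose(v, [1.3, -0.4], atol=1e-12)

    def test_attached_load_shifts_com(self, model):
        from reflexgait.simulation import attach_load

        st = ModelState(_walker_state().q, np.zeros(9))
        c0, _ = com_kinematics(model, st)
        c1, _ = com_kinematics(attach_load(model, 0.2), st)
        assert c1[0] != pytest.approx(c0[0])


class TestJointLimitTorque:
    def test_midrange_is_torque_free(self, model):
        st = ModelState(np.array([0, 1.0, 0, 0.2, 0.3, 0.1, 0.2, 0.3, 0.1]),
                        np.zeros(9))
        tau, hpe = joint_limit_torque(model, st)
        assert np.all(tau == 0.0) and hpe == 0.0

    def test_hyperextension_spring_law(self, model):
        delta = 0.1
        q = np.array([0, 1.0, 0, 0.2, -delta, 0.1, 0.2, 0.3, 0.1])
        st = ModelState(q, np.zeros(9))
        tau, hpe = joint_limit_torque(model, st)
        kappa = model.joint_limits["knee"].stiffness
        assert tau[1] == pytest.approx(kappa * delta)
        assert hpe == pytest.approx((kappa * delta) ** 2)

    def test_hpe_sums_squared_torques(self, model):
        q = np.array([0, 1.0, 0, 0.2, -0.1, 0.1, 0.2, -0.05, 0.1])
        st = ModelState(q, np.zeros(9))
        tau, hpe = joint_limit_torque(model, st)
        assert hpe == pytest.approx(tau[1] ** 2 + tau[4] ** 2)
        assert hpe == pytest.approx(np.sum(tau ** 2))


def test_model_total_mass_is_80_kg(model):
    assert model.body_mass == pytest.approx(80.0)
    assert len(model.segments) == 4   # trunk + thigh/shank/foot templates
    assert model.arrays().ndof == 9
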