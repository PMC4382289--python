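"""Low-level planar rigid-body dynamics kernels.

Everything here operates on a flat struct-of-arrays description of a planar
kinematic tree (one optional free base plus revolute joints) so the hot loop
can be JIT-compiled with numba. The walker model in :mod:`reflexgait.model_core`
compiles itself down to these arrays; tests also build small ad-hoc trees
(pendula, a free block) directly.

Tree description
----------------
parent : int64[nb]    parent body index, -1 for a root
jtype  : int64[nb]    0 = free planar joint (3 DOF: x, y, angle), 1 = pin (1 DOF)
jsign  : float64[nb]  sense of the pin coordinate (joint angle = jsign * q + joff)
joff   : float64[nb]  constant mount angle added to the joint coordinate
anchor : float64[nb,2] joint location in the parent frame (world frame for a
                       pinned root)
mass, inertia : float64[nb]  segment mass and moment of inertia about the COM
com_local : float64[nb,2]    COM location in the body frame
dof0 : int64[nb]      index of the body's first generalized coordinate

Bodies must be topologically ordered (parent index < child index).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def body_frames(parent, jtype, jsign, joff, anchor, dof0, q, qd):
    """Forward kinematics: world angle, angular rate, origin position and
    origin velocity of every body."""
    nb = parent.shape[0]
    phi = np.zeros(nb)
    w = np.zeros(nb)
    p = np.zeros((nb, 2))
    vo = np.zeros((nb, 2))
    for i in range(nb):
        pa = parent[i]
        d = dof0[i]
        if jtype[i] == 0:
            p[i, 0] = q[d]
            p[i, 1] = q[d + 1]
            phi[i] = q[d + 2] + joff[i]
            vo[i, 0] = qd[d]
            vo[i, 1] = qd[d + 1]
            w[i] = qd[d + 2]
        elif pa < 0:
            p[i, 0] = anchor[i, 0]
            p[i, 1] = anchor[i, 1]
            phi[i] = jsign[i] * q[d] + joff[i]
            w[i] = jsign[i] * qd[d]
        else:
            c = np.cos(phi[pa])
            s = np.sin(phi[pa])
            rx = c * anchor[i, 0] - s * anchor[i, 1]
            ry = s * anchor[i, 0] + c * anchor[i, 1]
            p[i, 0] = p[pa, 0] + rx
            p[i, 1] = p[pa, 1] + ry
            vo[i, 0] = vo[pa, 0] - w[pa] * ry
            vo[i, 1] = vo[pa, 1] + w[pa] * rx
            phi[i] = phi[pa] + jsign[i] * q[d] + joff[i]
            w[i] = w[pa] + jsign[i] * qd[d]
    return phi, w, p, vo


@njit(cache=True)
def inverse_dynamics(parent, jtype, jsign, joff, anchor, mass, inertia,
                     com_local, dof0, ndof, q, qd, qdd, gx, gy):
    """Generalized forces required to produce ``qdd`` at state (q, qd).

    Recursive Newton-Euler with gravity folded into the base acceleration.
    """
    nb = parent.shape[0]
    phi = np.zeros(nb)
    w = np.zeros(nb)
    al = np.zeros(nb)
    p = np.zeros((nb, 2))
    vo = np.zeros((nb, 2))
    ao = np.zeros((nb, 2))
    for i in range(nb):
        pa = parent[i]
        d = dof0[i]
        if jtype[i] == 0:
            p[i, 0] = q[d]
            p[i, 1] = q[d + 1]
            phi[i] = q[d + 2] + joff[i]
            vo[i, 0] = qd[d]
            vo[i, 1] = qd[d + 1]
            w[i] = qd[d + 2]
            ao[i, 0] = qdd[d] - gx
            ao[i, 1] = qdd[d + 1] - gy
            al[i] = qdd[d + 2]
        elif pa < 0:
            p[i, 0] = anchor[i, 0]
            p[i, 1] = anchor[i, 1]
            phi[i] = jsign[i] * q[d] + joff[i]
            w[i] = jsign[i] * qd[d]
            ao[i, 0] = -gx
            ao[i, 1] = -gy
            al[i] = jsign[i] * qdd[d]
        else:
            c = np.cos(phi[pa])
            s = np.sin(phi[pa])
            rx = c * anchor[i, 0] - s * anchor[i, 1]
            ry = s * anchor[i, 0] + c * anchor[i, 1]
            p[i, 0] = p[pa, 0] + rx
            p[i, 1] = p[pa, 1] + ry
            vo[i, 0] = vo[pa, 0] - w[pa] * ry
            vo[i, 1] = vo[pa, 1] + w[pa] * rx
            ao[i, 0] = ao[pa, 0] - al[pa] * ry - w[pa] * w[pa] * rx
            ao[i, 1] = ao[pa, 1] + al[pa] * rx - w[pa] * w[pa] * ry
            phi[i] = phi[pa] + jsign[i] * q[d] + joff[i]
            w[i] = w[pa] + jsign[i] * qd[d]
            al[i] = al[pa] + jsign[i] * qdd[d]

    F = np.zeros((nb, 2))
    N = np.zeros(nb)
    for i in range(nb):
        c = np.cos(phi[i])
        s = np.sin(phi[i])
        cx = c * com_local[i, 0] - s * com_local[i, 1]
        cy = s * com_local[i, 0] + c * com_local[i, 1]
        acx = ao[i, 0] - al[i] * cy - w[i] * w[i] * cx
        acy = ao[i, 1] + al[i] * cx - w[i] * w[i] * cy
        fx = mass[i] * acx
        fy = mass[i] * acy
        F[i, 0] += fx
        F[i, 1] += fy
        N[i] += inertia[i] * al[i] + cx * fy - cy * fx

    for i in range(nb - 1, -1, -1):
        pa = parent[i]
        if pa >= 0:
            F[pa, 0] += F[i, 0]
            F[pa, 1] += F[i, 1]
            rx = p[i, 0] - p[pa, 0]
            ry = p[i, 1] - p[pa, 1]
            N[pa] += N[i] + rx * F[i, 1] - ry * F[i, 0]

    tau = np.zeros(ndof)
    for i in range(nb):
        d = dof0[i]
        if jtype[i] == 0:
            tau[d] = F[i, 0]
            tau[d + 1] = F[i, 1]
            tau[d + 2] = N[i]
        else:
            tau[d] = jsign[i] * N[i]
    return tau


@njit(cache=True)
def mass_matrix(parent, jtype, jsign, joff, anchor, mass, inertia, com_local,
                dof0, ndof, q):
    M = np.zeros((ndof, ndof))
    zero = np.zeros(ndof)
    for j in range(ndof):
        ej = np.zeros(ndof)
        ej[j] = 1.0
        M[:, j] = inverse_dynamics(parent, jtype, jsign, joff, anchor, mass,
                                   inertia, com_local, dof0, ndof, q, zero,
                                   ej, 0.0, 0.0)
    return M


@njit(cache=True)
def bias_forces(parent, jtype, jsign, joff, anchor, mass, inertia, com_local,
                dof0, ndof, q, qd, gx, gy):
    """Coriolis/centrifugal plus gravity generalized forces (qdd = 0)."""
    zero = np.zeros(ndof)
    return inverse_dynamics(parent, jtype, jsign, joff, anchor, mass, inertia,
                            com_local, dof0, ndof, q, qd, zero, gx, gy)


@njit(cache=True)
def forward_dynamics_core(parent, jtype, jsign, joff, anchor, mass, inertia,
                          com_local, dof0, ndof, q, qd, applied, gx, gy):
    M = mass_matrix(parent, jtype, jsign, joff, anchor, mass, inertia,
                    com_local, dof0, ndof, q)
    b = bias_forces(parent, jtype, jsign, joff, anchor, mass, inertia,
                    com_local, dof0, ndof, q, qd, gx, gy)
    return np.linalg.solve(M, applied - b)


@njit(cache=True)
def point_state(parent, jtype, jsign, joff, anchor, dof0, q, qd, body,
                local_x, local_y):
    """World position and velocity of a point fixed in a body frame."""
    phi, w, p, vo = body_frames(parent, jtype, jsign, joff, anchor, dof0, q, qd)
    c = np.cos(phi[body])
    s = np.sin(phi[body])
    rx = c * local_x - s * local_y
    ry = s * local_x + c * local_y
    px = p[body, 0] + rx
    py = p[body, 1] + ry
    vx = vo[body, 0] - w[body] * ry
    vy = vo[body, 1] + w[body] * rx
    return px, py, vx, vy


@njit(cache=True)
def point_jacobian(parent, jtype, jsign, joff, anchor, dof0, ndof, phi, p,
                   body, px, py):
    """2 x ndof Jacobian of a world point carried by ``body``.

    ``phi``/``p`` come from :func:`body_frames` for the current q.
    """
    J = np.zeros((2, ndof))
    i = body
    while i >= 0:
        d = dof0[i]
        if jtype[i] == 0:
            J[0, d] = 1.0
            J[1, d + 1] = 1.0
            J[0, d + 2] += -(py - p[i, 1])
            J[1, d + 2] += (px - p[i, 0])
        else:
            J[0, d] += -jsign[i] * (py - p[i, 1])
            J[1, d] += jsign[i] * (px - p[i, 0])
        i = parent[i]
    return J


@njit(cache=True)
def com_state(parent, jtype, jsign, joff, anchor, mass, com_local, dof0, q, qd):
    """Whole-tree center of mass position and velocity."""
    phi, w, p, vo = body_frames(parent, jtype, jsign, joff, anchor, dof0, q, qd)
    nb = parent.shape[0]
    mtot = 0.0
    cx = 0.0
    cy = 0.0
    vx = 0.0
    vy = 0.0
    for i in range(nb):
        c = np.cos(phi[i])
        s = np.sin(phi[i])
        rx = c * com_local[i, 0] - s * com_local[i, 1]
        ry = s * com_local[i, 0] + c * com_local[i, 1]
        m = mass[i]
        mtot += m
        cx += m * (p[i, 0] + rx)
        cy += m * (p[i, 1] + ry)
        vx += m * (vo[i, 0] - w[i] * ry)
        vy += m * (vo[i, 1] + w[i] * rx)
    return cx / mtot, cy / mtot, vx / mtot, vy / mtot, mtot


@njit(cache=True)
def mechanical_energy(parent, jtype, jsign, joff, anchor, mass, inertia,
                      com_local, dof0, q, qd, gx, gy):
    """Kinetic plus gravitational potential energy of the tree."""
    phi, w, p, vo = body_frames(parent, jtype, jsign, joff, anchor, dof0, q, qd)
    nb = parent.shape[0]
    E = 0.0
    for i in range(nb):
        c = np.cos(phi[i])
        s = np.sin(phi[i])
        rx = c * com_local[i, 0] - s * com_local[i, 1]
        ry = s * com_local[i, 0] + c * com_local[i, 1]
        vx = vo[i, 0] - w[i] * ry
        vy = vo[i, 1] + w[i] * rx
        E += 0.5 * mass[i] * (vx * vx + vy * vy) + 0.5 * inertia[i] * w[i] * w[i]
        E -= mass[i] * (gx * (p[i, 0] + rx) + gy * (p[i, 1] + ry))
    return E
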