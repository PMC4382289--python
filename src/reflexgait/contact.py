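"""Foot-ground interaction.

Normal forces follow a compliant Hunt-Crossley law at two small spheres per
foot (heel and ball); tangential forces use a smooth Stribeck-style friction
coefficient blending static to dynamic friction with a viscous term. Negative
Hunt-Crossley values (fast retraction) are clamped to zero: the unclamped
formula can produce adhesion, which is unphysical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine


@dataclass(frozen=True)
class ContactParams:
    """Hunt-Crossley and friction material parameters.

    mu_v scales a term ``mu_v * |slip speed|`` added to the friction
    coefficient, i.e. it carries units of s/m; the transition speed ``v_t``
    sets the slip-speed scale of the static/dynamic blend.
    """

    k: float = 9.4281e5       # N m^-1.5
    c: float = 2.0            # (m/s)^-1
    mu_s: float = 0.8
    mu_d: float = 0.8
    mu_v: float = 0.5
    v_t: float = 0.1          # m/s
    sphere_radius: float = 0.01
    heel_offset: tuple[float, float] = (-0.06, -0.06)
    ball_offset: tuple[float, float] = (0.14, -0.06)
    on_threshold: float = 20.0   # N; controller contact trigger
    off_threshold: float = 5.0   # N; release hysteresis

    def __post_init__(self):
        if self.k <= 0 or self.c < 0:
            raise ValueError("require k > 0 and c >= 0")
        if not (self.mu_s >= self.mu_d >= 0.0):
            raise ValueError("require mu_s >= mu_d >= 0")
        if self.v_t <= 0 or self.sphere_radius <= 0:
            raise ValueError("require v_t > 0 and sphere_radius > 0")


@dataclass
class SphereForce:
    """Per-sphere contact result (world frame)."""

    point: np.ndarray
    normal: float
    tangential: float
    penetration: float


@dataclass
class ContactForce:
    """Resultant ground reaction on one foot."""

    grf_y: float
    grf_x: float
    cop_x: float
    spheres: list

    @property
    def in_contact(self) -> bool:
        return self.grf_y > 0.0


def normal_force(h: float, hdot: float, params: ContactParams) -> float:
    """Hunt-Crossley normal force ``k h^1.5 (1 + 1.5 c hdot)``.

    ``h`` is ground penetration (positive into the ground) and ``hdot`` its
    rate. Zero for h <= 0 and clamped below at zero.
    """
    if h <= 0.0:
        return 0.0
    f = params.k * h ** 1.5 * (1.0 + 1.5 * params.c * hdot)
    return f if f > 0.0 else 0.0


def friction_coefficient(xdot: float, params: ContactParams) -> float:
    """Smooth slip-velocity-dependent friction coefficient (odd in xdot).

    Piecewise-cubic Stribeck blend: stiction ramp up to mu_s at the
    transition speed v_t, blend down to mu_d by 3 v_t, plus the viscous
    contribution mu_v * |xdot|. Continuously differentiable.
    """
    s = abs(xdot) / params.v_t
    if s <= 1.0:
        mu = params.mu_s * s * s * (3.0 - 2.0 * s)
    elif s <= 3.0:
        u = (s - 1.0) / 2.0
        mu = params.mu_s - (params.mu_s - params.mu_d) * u * u * (3.0 - 2.0 * u)
    else:
        mu = params.mu_d
    mu += params.mu_v * abs(xdot)
    return mu if xdot >= 0.0 else -mu


def friction_force(xdot: float, normal: float, params: ContactParams) -> float:
    """Tangential force opposing slip; zero at zero load or zero slip."""
    if normal <= 0.0:
        return 0.0
    return -friction_coefficient(xdot, params) * normal


def sphere_contact(px, py, vx, vy, params: ContactParams,
                   ground_height: float = 0.0, ground_angle: float = 0.0):
    """Normal and tangential force (world frame) at one sphere center.

    Penetration is measured from the sphere's lowest point against a plane
    through ``(0, ground_height)`` inclined by ``ground_angle`` (rad). For
    a tilted plane, position and velocity are rotated into the plane frame
    and the resulting force rotated back.
    """
    if ground_angle != 0.0:
        ca, sa = np.cos(ground_angle), np.sin(ground_angle)
        px, py = ca * px + sa * py, -sa * px + ca * py
        vx, vy = ca * vx + sa * vy, -sa * vx + ca * vy
    h = ground_height - (py - params.sphere_radius)
    fn = normal_force(h, -vy, params)
    ft = friction_force(vx, fn, params)
    if ground_angle != 0.0:
        ca, sa = np.cos(ground_angle), np.sin(ground_angle)
        fw = (ca * ft - sa * fn, sa * ft + ca * fn)
    else:
        fw = (ft, fn)
    return fn, ft, h, fw


def foot_contact_forces(model, state, params: ContactParams | None = None,
                        ground_height: float = 0.0):
    """Resultant GRF per foot plus the generalized-force projection.

    Returns ``(forces, Q)`` where ``forces`` is a dict with keys 'r' and 'l'
    holding :class:`ContactForce` and ``Q`` is the 9-vector of generalized
    contact forces.
    """
    if params is None:
        params = model.contact
    arr = model.arrays()
    phi, w, p, vo = _engine.body_frames(*arr.tree, arr.dof0, state.q,
                                        state.qdot)
    bodies, offsets = model.sphere_arrays()
    Q = np.zeros(arr.ndof)
    feet = {"r": [], "l": []}
    for b, off in zip(bodies, offsets):
        px, py, vx, vy = _engine.point_state(*arr.tree, arr.dof0, state.q,
                                             state.qdot, b, off[0], off[1])
        fn, ft, h, _ = sphere_contact(px, py, vx, vy, params, ground_height)
        feet["r" if b == 3 else "l"].append(
            SphereForce(np.array([px, py]), fn, ft, h))
        if fn > 0.0:
            J = _engine.point_jacobian(*arr.tree, arr.dof0, arr.ndof, phi, p,
                                       b, px, py)
            Q += J.T @ np.array([ft, fn])
    out = {}
    for leg, spheres in feet.items():
        fy = sum(s.normal for s in spheres)
        fx = sum(s.tangential for s in spheres)
        cop = (sum(s.normal * s.point[0] for s in spheres) / fy
               if fy > 0.0 else np.nan)
        out[leg] = ContactForce(grf_y=fy, grf_x=fx, cop_x=cop, spheres=spheres)
    return out, Q
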