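"""Planar 7-segment, 9-DOF skeletal model.

Coordinate convention: x forward, y up, z out of the sagittal plane; angles
follow the right-hand rule about z. Joint coordinates are reported in the
gait-figure convention: hip flexion, knee flexion and ankle dorsiflexion are
positive. Generalized coordinates::

    q = [trunk_x, trunk_y, trunk_pitch,
         hip_R, knee_R, ankle_R, hip_L, knee_L, ankle_L]

Trunk pitch is the world angle of the trunk segment (0 = upright, positive =
backward lean). The trunk frame origin is at the hip joint center, which both
legs share.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import NamedTuple

import numpy as np
import yaml

from . import _engine
from .contact import ContactParams

DOF_NAMES = ("trunk_x", "trunk_y", "trunk_pitch", "hip_r", "knee_r",
             "ankle_r", "hip_l", "knee_l", "ankle_l")
JOINT_DOFS = (3, 4, 5, 6, 7, 8)  # leg joints with limits and muscle torques
JOINT_NAMES = ("hip_r", "knee_r", "ankle_r", "hip_l", "knee_l", "ankle_l")

# sense of the internal rotation for each leg joint under the sign convention
# above: hip flexion +z, knee flexion -z, ankle dorsiflexion +z
_JOINT_SIGNS = (1.0, -1.0, 1.0)


@dataclass(frozen=True)
class SegmentSpec:
    """Inertial and geometric description of one rigid segment."""

    name: str
    mass: float
    com_offset: tuple[float, float]
    inertia_zz: float
    length: float

    def __post_init__(self):
        if self.mass <= 0 or self.inertia_zz <= 0 or self.length <= 0:
            raise ValueError(f"segment {self.name}: mass, inertia and length "
                             "must be positive")


@dataclass(frozen=True)
class JointLimit:
    lower: float          # rad
    upper: float          # rad
    stiffness: float      # N m / rad beyond the stop
    damping: float        # N m s / rad while beyond the stop


class ModelArrays(NamedTuple):
    """Flat tree description consumed by the :mod:`reflexgait._engine` kernels."""

    parent: np.ndarray
    jtype: np.ndarray
    jsign: np.ndarray
    joff: np.ndarray
    anchor: np.ndarray
    mass: np.ndarray
    inertia: np.ndarray
    com_local: np.ndarray
    dof0: np.ndarray
    ndof: int

    @property
    def tree(self):
        return (self.parent, self.jtype, self.jsign, self.joff, self.anchor)

    @property
    def full(self):
        return (self.parent, self.jtype, self.jsign, self.joff, self.anchor,
                self.mass, self.inertia, self.com_local, self.dof0, self.ndof)


def build_tree(bodies) -> ModelArrays:
    """Assemble :class:`ModelArrays` from a list of body dicts.

    Each dict: ``parent`` (int, -1 for root), ``joint`` ('free' or 'pin'),
    ``mass``, ``inertia``, ``com`` (2-seq), ``anchor`` (2-seq), optional
    ``sign`` and ``offset`` for pin joints. Mainly used by the walker builder
    and by tests that need small ad-hoc mechanisms (pendula, a free block).
    """
    nb = len(bodies)
    parent = np.empty(nb, dtype=np.int64)
    jtype = np.empty(nb, dtype=np.int64)
    jsign = np.ones(nb)
    joff = np.zeros(nb)
    anchor = np.zeros((nb, 2))
    mass = np.empty(nb)
    inertia = np.empty(nb)
    com_local = np.zeros((nb, 2))
    dof0 = np.empty(nb, dtype=np.int64)
    d = 0
    for i, b in enumerate(bodies):
        parent[i] = b.get("parent", -1)
        if parent[i] >= i:
            raise ValueError("bodies must be topologically ordered")
        jtype[i] = 0 if b.get("joint", "pin") == "free" else 1
        jsign[i] = b.get("sign", 1.0)
        joff[i] = b.get("offset", 0.0)
        anchor[i] = np.asarray(b.get("anchor", (0.0, 0.0)), dtype=float)
        mass[i] = b["mass"]
        inertia[i] = b["inertia"]
        com_local[i] = np.asarray(b.get("com", (0.0, 0.0)), dtype=float)
        dof0[i] = d
        d += 3 if jtype[i] == 0 else 1
    return ModelArrays(parent, jtype, jsign, joff, anchor, mass, inertia,
                       com_local, dof0, d)


@dataclass
class ModelState:
    """Full kinematic state: 9 coordinates, 9 velocities, time."""

    q: np.ndarray
    qdot: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.qdot = np.asarray(self.qdot, dtype=float)
        if self.q.shape != (9,) or self.qdot.shape != (9,):
            raise ValueError("q and qdot must be 9-vectors")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qdot))):
            raise ValueError("non-finite model state")

    def mirrored(self) -> "ModelState":
        """Swap the left and right legs."""
        perm = [0, 1, 2, 6, 7, 8, 3, 4, 5]
        return ModelState(self.q[perm].copy(), self.qdot[perm].copy(), self.t)


@dataclass
class SkeletonModel:
    """The 7-segment planar walker plus its environment parameters."""

    segments: dict[str, SegmentSpec]
    joint_limits: dict[str, JointLimit]
    gravity: np.ndarray
    heel_offset: np.ndarray
    ball_offset: np.ndarray
    contact: ContactParams
    extra_trunk_mass: float = 0.0       # backpack load, kg
    extra_trunk_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(2))  # in trunk frame
    extra_trunk_inertia: float = 0.0    # kg m^2 about the load point
    _arrays: ModelArrays | None = field(default=None, repr=False)

    # ---------------------------------------------------------- construction
    @classmethod
    def from_yaml(cls, path=None) -> "SkeletonModel":
        """Load the model description; the packaged default if no path."""
        if path is None:
            text = (resources.files("reflexgait") / "config/model.yaml").read_text()
            cfg = yaml.safe_load(text)
        else:
            with open(path) as fh:
                cfg = yaml.safe_load(fh)
        segs = {}
        for name, s in cfg["segments"].items():
            segs[name] = SegmentSpec(name=name, mass=float(s["mass"]),
                                     com_offset=tuple(s["com_offset"]),
                                     inertia_zz=float(s["inertia_zz"]),
                                     length=float(s["length"]))
        lims = {}
        for name, j in cfg["joints"].items():
            lo, hi = (math.radians(v) for v in j["limits_deg"])
            lims[name] = JointLimit(lo, hi, float(j["stiffness"]),
                                    float(j["damping"]))
        c = cfg["contact"]
        fg = cfg["foot_geometry"]
        contact = ContactParams(
            k=float(c["stiffness"]), c=float(c["dissipation"]),
            mu_s=float(c["mu_static"]), mu_d=float(c["mu_dynamic"]),
            mu_v=float(c["mu_viscous"]), v_t=float(c["transition_speed"]),
            sphere_radius=float(c["sphere_radius"]),
            heel_offset=tuple(fg["heel_offset"]),
            ball_offset=tuple(fg["ball_offset"]),
            on_threshold=float(c.get("contact_on_threshold", 20.0)),
            off_threshold=float(c.get("contact_off_threshold", 5.0)),
        )
        return cls(segments=segs, joint_limits=lims,
                   gravity=np.asarray(cfg["gravity"], dtype=float),
                   heel_offset=np.asarray(fg["heel_offset"], dtype=float),
                   ball_offset=np.asarray(fg["ball_offset"], dtype=float),
                   contact=contact)

    @classmethod
    def default(cls) -> "SkeletonModel":
        return cls.from_yaml()

    # ------------------------------------------------------------ properties
    @property
    def body_mass(self) -> float:
        """Skeleton mass without any attached load, kg."""
        segs = self.segments
        return (segs["trunk"].mass
                + 2.0 * (segs["thigh"].mass + segs["shank"].mass
                         + segs["foot"].mass))

    @property
    def total_mass(self) -> float:
        return self.body_mass + self.extra_trunk_mass

    @property
    def head_local(self) -> np.ndarray:
        """Top of the trunk segment in the trunk frame."""
        return np.array([0.0, self.segments["trunk"].length])

    def arrays(self) -> ModelArrays:
        if self._arrays is None:
            self._arrays = self._compile()
        return self._arrays

    def _compile(self) -> ModelArrays:
        tr, th, sh, ft = (self.segments[n] for n in
                          ("trunk", "thigh", "shank", "foot"))
        # fold an attached trunk load into the trunk segment (composite body)
        m_tr = tr.mass + self.extra_trunk_mass
        com = np.asarray(tr.com_offset, dtype=float)
        if self.extra_trunk_mass > 0.0:
            load = com + self.extra_trunk_offset
            com_new = (tr.mass * com + self.extra_trunk_mass * load) / m_tr
            # parallel-axis both contributions to the composite COM
            i_tr = (tr.inertia_zz
                    + tr.mass * np.sum((com - com_new) ** 2)
                    + self.extra_trunk_inertia
                    + self.extra_trunk_mass * np.sum((load - com_new) ** 2))
            com = com_new
        else:
            i_tr = tr.inertia_zz
        hip_s, knee_s, ankle_s = _JOINT_SIGNS
        bodies = [
            dict(joint="free", mass=m_tr, inertia=i_tr, com=tuple(com)),
        ]
        for leg_parent in (0, 0):
            thigh_i = len(bodies)
            bodies.append(dict(parent=leg_parent, joint="pin", sign=hip_s,
                               anchor=(0.0, 0.0), mass=th.mass,
                               inertia=th.inertia_zz, com=tuple(th.com_offset)))
            bodies.append(dict(parent=thigh_i, joint="pin", sign=knee_s,
                               anchor=(0.0, -th.length), mass=sh.mass,
                               inertia=sh.inertia_zz, com=tuple(sh.com_offset)))
            bodies.append(dict(parent=thigh_i + 1, joint="pin", sign=ankle_s,
                               anchor=(0.0, -sh.length), mass=ft.mass,
                               inertia=ft.inertia_zz, com=tuple(ft.com_offset)))
        return build_tree(bodies)

    def limit_arrays(self):
        """(lo, hi, k, c) per generalized coordinate; +-inf where unlimited."""
        lo = np.full(9, -np.inf)
        hi = np.full(9, np.inf)
        k = np.zeros(9)
        c = np.zeros(9)
        for j, name in zip(JOINT_DOFS, JOINT_NAMES):
            lim = self.joint_limits[name.split("_")[0]]
            lo[j], hi[j], k[j], c[j] = (lim.lower, lim.upper, lim.stiffness,
                                        lim.damping)
        return lo, hi, k, c

    def sphere_arrays(self):
        """Contact sphere body indices and foot-frame offsets (heel, ball per leg)."""
        body = np.array([3, 3, 6, 6], dtype=np.int64)
        offs = np.array([self.heel_offset, self.ball_offset,
                         self.heel_offset, self.ball_offset])
        return body, offs


# -------------------------------------------------------------- operations

def forward_dynamics(model: SkeletonModel, state: ModelState,
                     generalized_forces: np.ndarray) -> np.ndarray:
    """Accelerations q̈ from the planar equations of motion.

    ``generalized_forces`` must already include muscle joint torques,
    contact generalized forces and joint-limit torques.
    """
    Q = np.asarray(generalized_forces, dtype=float)
    if Q.shape != (9,):
        raise ValueError("generalized_forces must be a 9-vector")
    arr = model.arrays()
    M = _engine.mass_matrix(*arr.full[:-1], arr.ndof, state.q)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("singular mass matrix (malformed inertia)")
    b = _engine.bias_forces(*arr.full[:-1], arr.ndof, state.q, state.qdot,
                            model.gravity[0], model.gravity[1])
    return np.linalg.solve(M, Q - b)


def joint_limit_torque(model: SkeletonModel, state: ModelState):
    """One-sided spring-damper stop torques on the 6 leg joints.

    Returns ``(torques, hpe_instant)`` where ``torques`` holds the hip/knee/
    ankle limit torques for both legs (N m, in joint coordinates) and
    ``hpe_instant`` is the summed squared limit torque (the hyperextension
    penalty integrand).
    """
    lo, hi, k, c = model.limit_arrays()
    tau = np.zeros(6)
    for out_i, j in enumerate(JOINT_DOFS):
        qj = state.q[j]
        if qj > hi[j]:
            tau[out_i] = -k[j] * (qj - hi[j]) - c[j] * state.qdot[j]
        elif qj < lo[j]:
            tau[out_i] = -k[j] * (qj - lo[j]) - c[j] * state.qdot[j]
    return tau, float(np.sum(tau ** 2))


def com_kinematics(model: SkeletonModel, state: ModelState):
    """Whole-body COM position and velocity (includes any attached load)."""
    arr = model.arrays()
    cx, cy, vx, vy, _ = _engine.com_state(*arr.tree, arr.mass, arr.com_local,
                                          arr.dof0, state.q, state.qdot)
    return np.array([cx, cy]), np.array([vx, vy])


def mechanical_energy(model: SkeletonModel, state: ModelState) -> float:
    arr = model.arrays()
    return _engine.mechanical_energy(*arr.full[:-2], arr.dof0, state.q,
                                     state.qdot, model.gravity[0],
                                     model.gravity[1])
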