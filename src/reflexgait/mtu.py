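"""Hill-type musculotendon units.

Each MTU is a contractile fiber (force-length bell, force-velocity curve,
parallel passive elasticity) in series with a quadratic elastic tendon.
First-order activation dynamics turn neural excitation into activation.
The fiber length l_ce is a state variable: at every step the tendon force is
computed from the series stretch, and the fiber velocity is recovered by
inverting the force-velocity relation so that fiber and tendon forces agree
(a rigid-tendon fallback is available via ``rigid_tendon=True``).

Muscle order (per leg): ILPSO, GMAX, HAMS, RF, VAS, GAS, SOL, TA. HAMS, RF
and GAS are biarticular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from ._engine import njit

MUSCLES = ("ILPSO", "GMAX", "HAMS", "RF", "VAS", "GAS", "SOL", "TA")
N_MUSCLES = len(MUSCLES)
JOINT_INDEX = {"hip": 0, "knee": 1, "ankle": 2}

# default Hill-curve shape constants; overridable from the YAML table
FL_WIDTH = 0.56
FL_LOGMIN = float(np.log(0.05))
FV_SHAPE = 5.0
FV_ECC_MAX = 1.5
PE_STRAIN = 0.7
TENDON_STRAIN = 0.04


@dataclass(frozen=True)
class MomentArm:
    joint: str
    direction: float          # +1: shortening drives the joint positive
    r0: float                 # m
    shape: str = "constant"   # 'constant' or 'cosine'
    c: float = 1.0            # angular scale of the cosine shape
    qc: float = 0.0           # center angle of the cosine shape, rad


@dataclass(frozen=True)
class MTUParams:
    name: str
    F_max: float
    l_opt: float
    v_max: float              # l_opt / s
    tendon_slack: float
    tau_act: float = 0.01
    u0: float = 0.01
    joints: tuple = ()

    def __post_init__(self):
        if min(self.F_max, self.l_opt, self.v_max) <= 0:
            raise ValueError(f"{self.name}: F_max, l_opt, v_max must be > 0")


@dataclass
class MTUState:
    a: float                  # activation in [0, 1]
    l_ce: float               # fiber length, m
    F_mtu_norm: float = 0.0   # force / F_max


# ------------------------------------------------------------- Hill curves

@njit(cache=True)
def force_length(lnorm, width=FL_WIDTH, logmin=FL_LOGMIN):
    """Active force-length bell; 1 at l_opt, ~0.05 at a strain of ``width``."""
    x = np.abs(lnorm - 1.0) / width
    return np.exp(logmin * x * x * x)


@njit(cache=True)
def force_velocity(wnorm, K=FV_SHAPE, N=FV_ECC_MAX):
    """Force-velocity curve vs normalized fiber velocity w = v_ce / v_max.

    Classic Hill hyperbola for shortening (w < 0, zero at w = -1), smooth
    saturating eccentric branch approaching N, C1 at w = 0.
    """
    if wnorm <= -1.0:
        return 0.0
    if wnorm <= 0.0:
        return (1.0 + wnorm) / (1.0 - K * wnorm)
    gamma = (1.0 + K) / (N - 1.0)
    return N - (N - 1.0) / (1.0 + gamma * wnorm)


@njit(cache=True)
def force_velocity_inverse(g, K=FV_SHAPE, N=FV_ECC_MAX):
    """Normalized fiber velocity at which the fv curve equals ``g``."""
    if g <= 0.0:
        return -1.0
    if g <= 1.0:
        return (g - 1.0) / (1.0 + K * g)
    gmax = N - 1e-3
    if g > gmax:
        g = gmax
    gamma = (1.0 + K) / (N - 1.0)
    return ((N - 1.0) / (N - g) - 1.0) / gamma


@njit(cache=True)
def passive_force(lnorm, strain=PE_STRAIN):
    """Normalized parallel-elastic force; zero below l_opt, quadratic above."""
    if lnorm <= 1.0:
        return 0.0
    e = (lnorm - 1.0) / strain
    return e * e


@njit(cache=True)
def tendon_force(l_se, slack, strain=TENDON_STRAIN):
    """Normalized series-elastic force; quadratic in tendon strain."""
    if l_se <= slack:
        return 0.0
    e = (l_se - slack) / (slack * strain)
    return e * e


@njit(cache=True)
def fiber_velocity_from_equilibrium(a, l_ce, l_mtu, F_max, l_opt, v_max,
                                    slack):
    """Solve the tendon-equilibrium condition for the fiber velocity.

    Returns ``(F_norm, v_ce)``: the MTU (tendon) force normalized by F_max
    and the fiber lengthening rate in m/s.
    """
    lnorm = l_ce / l_opt
    f_se = tendon_force(l_mtu - l_ce, slack)
    denom = a * force_length(lnorm)
    g = (f_se - passive_force(lnorm)) / max(denom, 0.01)
    if g < 0.0:
        g = 0.0
    w = force_velocity_inverse(g)
    # bound the lengthening rate at v_max: the inverse blows up near the
    # eccentric plateau and unbounded fiber rates destabilize integration
    if w > 1.0:
        w = 1.0
    # soft fiber-length bounds: never integrate out of [0.3, 1.9] l_opt
    if lnorm <= 0.3 and w < 0.0:
        w = 0.0
    if lnorm >= 1.9 and w > 0.0:
        w = 0.0
    return f_se, w * v_max * l_opt


# -------------------------------------------------------------- operations

def activation_dynamics(a: float, u: float, dt: float, tau: float) -> float:
    """First-order approach of activation toward the (clipped) excitation.

    Exact exponential update, so the result stays in [0, 1] for any dt.
    """
    u = min(max(u, 0.0), 1.0)
    return u + (a - u) * np.exp(-dt / tau)


def fiber_force(params: MTUParams, a: float, l_ce: float,
                v_ce: float) -> float:
    """Active + passive fiber force (N) at the given state."""
    lnorm = l_ce / params.l_opt
    wnorm = v_ce / (params.v_max * params.l_opt)
    return params.F_max * (a * force_length(lnorm) * force_velocity(wnorm)
                           + passive_force(lnorm))


def mtu_force(params: MTUParams, state: MTUState, l_mtu: float,
              v_mtu: float, rigid_tendon: bool = False):
    """MTU force and fiber lengthening rate at the current path length.

    Elastic-tendon mode (default) enforces fiber/tendon force equilibrium
    and returns the implied fiber velocity; rigid-tendon mode pins the
    fiber to ``l_mtu - tendon_slack``.
    """
    if not np.isfinite(l_mtu):
        raise ValueError("non-finite MTU path length")
    if rigid_tendon:
        l_ce = l_mtu - params.tendon_slack
        return fiber_force(params, state.a, l_ce, v_mtu), v_mtu
    f_norm, v_ce = fiber_velocity_from_equilibrium(
        state.a, state.l_ce, l_mtu, params.F_max, params.l_opt, params.v_max,
        params.tendon_slack)
    return f_norm * params.F_max, v_ce


# ---------------------------------------------------------------- geometry

def moment_arm(arm: MomentArm, q: float) -> float:
    if arm.shape == "constant":
        return arm.r0
    return arm.r0 * np.cos(arm.c * (q - arm.qc))


def path_length_contribution(arm: MomentArm, q: float) -> float:
    """Exact integral of -dir * r(q) dq from the reference pose q = 0."""
    if arm.shape == "constant":
        return -arm.direction * arm.r0 * q
    return -arm.direction * (arm.r0 / arm.c) * (
        np.sin(arm.c * (q - arm.qc)) - np.sin(arm.c * (-arm.qc)))


@dataclass
class MuscleSet:
    """The 8-muscle parameter table for one leg, with packed arrays for the
    simulation kernel."""

    params: dict[str, MTUParams]
    curves: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path=None) -> "MuscleSet":
        if path is None:
            text = (resources.files("reflexgait")
                    / "config/mtu_params.yaml").read_text()
            cfg = yaml.safe_load(text)
        else:
            with open(path) as fh:
                cfg = yaml.safe_load(fh)
        params = {}
        for name in MUSCLES:
            m = cfg["muscles"][name]
            arms = tuple(
                MomentArm(joint=j["joint"], direction=float(j["dir"]),
                          r0=float(j["r0"]), shape=j.get("shape", "constant"),
                          c=float(j.get("c", 1.0)), qc=float(j.get("qc", 0.0)))
                for j in m["joints"])
            params[name] = MTUParams(
                name=name, F_max=float(m["F_max"]), l_opt=float(m["l_opt"]),
                v_max=float(m["v_max"]),
                tendon_slack=float(m["tendon_slack"]),
                tau_act=float(m.get("tau_act", 0.01)),
                u0=float(m.get("u0", 0.01)), joints=arms)
        return cls(params=params, curves=dict(cfg.get("curves", {})))

    @classmethod
    def default(cls) -> "MuscleSet":
        return cls.from_yaml()

    def __getitem__(self, name: str) -> MTUParams:
        return self.params[name]

    # reference path length at the zero pose: slack + optimal fiber length
    def reference_length(self, name: str) -> float:
        p = self.params[name]
        return p.tendon_slack + p.l_opt

    def path_length(self, name: str, q_leg: np.ndarray) -> float:
        """MTU path length at leg joint angles [hip, knee, ankle] (rad)."""
        p = self.params[name]
        l = self.reference_length(name)
        for arm in p.joints:
            l += path_length_contribution(arm, q_leg[JOINT_INDEX[arm.joint]])
        return l

    def path_velocity(self, name: str, q_leg, qd_leg) -> float:
        p = self.params[name]
        v = 0.0
        for arm in p.joints:
            j = JOINT_INDEX[arm.joint]
            v += -arm.direction * moment_arm(arm, q_leg[j]) * qd_leg[j]
        return v

    def packed(self):
        """Flat arrays for the jitted rollout kernel.

        Returns a dict of arrays indexed [muscle, slot] with up to two
        moment-arm slots per muscle.
        """
        n = N_MUSCLES
        out = {
            "F_max": np.zeros(n), "l_opt": np.zeros(n), "v_max": np.zeros(n),
            "slack": np.zeros(n), "tau": np.zeros(n), "u0": np.zeros(n),
            "n_arms": np.zeros(n, dtype=np.int64),
            "arm_joint": np.zeros((n, 2), dtype=np.int64),
            "arm_dir": np.zeros((n, 2)), "arm_r0": np.zeros((n, 2)),
            "arm_cos": np.zeros((n, 2), dtype=np.int64),
            "arm_c": np.ones((n, 2)), "arm_qc": np.zeros((n, 2)),
            "l_ref": np.zeros(n),
        }
        for i, name in enumerate(MUSCLES):
            p = self.params[name]
            out["F_max"][i] = p.F_max
            out["l_opt"][i] = p.l_opt
            out["v_max"][i] = p.v_max
            out["slack"][i] = p.tendon_slack
            out["tau"][i] = p.tau_act
            out["u0"][i] = p.u0
            out["n_arms"][i] = len(p.joints)
            out["l_ref"][i] = self.reference_length(name)
            for s, arm in enumerate(p.joints):
                out["arm_joint"][i, s] = JOINT_INDEX[arm.joint]
                out["arm_dir"][i, s] = arm.direction
                out["arm_r0"][i, s] = arm.r0
                out["arm_cos"][i, s] = 0 if arm.shape == "constant" else 1
                out["arm_c"][i, s] = arm.c
                out["arm_qc"][i, s] = arm.qc
        return out


def muscle_joint_torques(muscles: MuscleSet, forces: dict[str, float],
                         q_leg: np.ndarray) -> np.ndarray:
    """Joint torques [hip, knee, ankle] from per-muscle MTU forces (N)."""
    tau = np.zeros(3)
    for name, F in forces.items():
        for arm in muscles[name].joints:
            j = JOINT_INDEX[arm.joint]
            tau[j] += arm.direction * moment_arm(arm, q_leg[j]) * F
    return tau
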