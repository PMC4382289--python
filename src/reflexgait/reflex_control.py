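"""Delayed reflex control laws and the per-leg gait-mode machine.

Muscle excitations are a sum of a small fixed baseline u0, per-mode constant
stim offsets, and force / stretch / PD / inhibition feedback laws operating
on sensory signals delayed by fixed, muscle-specific propagation times
(5 ms for ILPSO/GMAX/HAMS/RF, 10 ms for VAS, 20 ms for GAS/SOL/TA). Which
law acts on which muscle in which gait mode is declared in
``config/controller.yaml``; the free parameters enumerated there (plus the
swing trigger distance d_swing) form the controller part of the design
vector. Both legs share one parameter set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .mtu import MUSCLES, N_MUSCLES

N_MODES = 3
MODE_NAMES = ("stance", "early_swing", "late_swing")

# PD feature codes used in the packed arrays
FEAT_NONE, FEAT_TRUNK, FEAT_HIP, FEAT_KNEE = 0, 1, 2, 3
_FEATURES = {"trunk_lean": FEAT_TRUNK, "hip": FEAT_HIP, "knee": FEAT_KNEE}


class GaitMode(enum.IntEnum):
    STANCE = 0
    EARLY_SWING = 1
    LATE_SWING = 2


# ------------------------------------------------------------ control laws

def force_feedback(G_F: float, F_mtu_delayed: float) -> float:
    """Excitation proportional to the muscle's own delayed normalized force."""
    return G_F * F_mtu_delayed


def stretch_feedback(G_L: float, l_ce_delayed: float, H: float) -> float:
    """Excitation proportional to delayed fiber stretch beyond threshold H."""
    return G_L * max(l_ce_delayed - H, 0.0)


def pd_feedback(K_p: float, K_d: float, theta_delayed: float,
                thetadot_delayed: float, theta_desired: float) -> float:
    """Rectified PD on a delayed angular feature."""
    return max(K_p * (theta_delayed - theta_desired)
               + K_d * thetadot_delayed, 0.0)


def update_gait_mode(mode: GaitMode, foot_in_contact: bool, ankle_x: float,
                     com_x: float, d_swing: float) -> GaitMode:
    """Three-mode state machine per leg.

    Contact on -> STANCE; contact off -> EARLY_SWING; EARLY -> LATE when
    the ankle joint center moves more than d_swing ahead of the COM.
    """
    if foot_in_contact:
        return GaitMode.STANCE
    if mode == GaitMode.STANCE:
        return GaitMode.EARLY_SWING
    if mode == GaitMode.EARLY_SWING and (ankle_x - com_x) > d_swing:
        return GaitMode.LATE_SWING
    return mode


# -------------------------------------------------------- parameter layout

@dataclass(frozen=True)
class _Slot:
    """Where one free scalar lands in the packed controller arrays."""

    array: str               # packed array name
    muscle: int
    mode: int
    label: str


@dataclass
class ControlParams:
    """Packed per-(muscle, mode) controller arrays plus d_swing.

    Arrays are indexed [muscle, mode] over the 8 shared muscles and the 3
    gait modes; both legs read the same arrays.
    """

    C: np.ndarray
    GF: np.ndarray
    GL: np.ndarray
    H: np.ndarray
    GS: np.ndarray             # suppression gain
    sup_source: np.ndarray     # muscle index of the inhibiting force, -1 none
    KP: np.ndarray
    KD: np.ndarray
    theta_target: np.ndarray
    pd_feature: np.ndarray
    pd_sign: np.ndarray
    C_gate: np.ndarray         # 1: constant scales with (1 - load_share)
    KG: np.ndarray             # knee-guard gain
    guard_angle: float
    u0: np.ndarray
    delays_s: np.ndarray
    d_swing: float

    @classmethod
    def zeros(cls, u0=None, delays_s=None, guard_angle=0.25):
        z = lambda: np.zeros((N_MUSCLES, N_MODES))
        return cls(C=z(), GF=z(), GL=z(), H=np.ones((N_MUSCLES, N_MODES)),
                   GS=z(),
                   sup_source=np.full((N_MUSCLES, N_MODES), -1, dtype=np.int64),
                   KP=z(), KD=z(), theta_target=z(),
                   pd_feature=np.zeros((N_MUSCLES, N_MODES), dtype=np.int64),
                   pd_sign=np.ones((N_MUSCLES, N_MODES)),
                   C_gate=np.zeros((N_MUSCLES, N_MODES), dtype=np.int64),
                   KG=z(),
                   guard_angle=guard_angle,
                   u0=(np.full(N_MUSCLES, 0.01) if u0 is None
                       else np.asarray(u0, dtype=float)),
                   delays_s=(np.full(N_MUSCLES, 0.005) if delays_s is None
                             else np.asarray(delays_s, dtype=float)),
                   d_swing=0.15)


def muscle_excitation(params: ControlParams, m: int, mode: int,
                      F_del: float, l_del: float, theta_del: float,
                      thetadot_del: float, F_sup_del: float,
                      q_knee_del: float, qd_knee_del: float,
                      load_share: float = 1.0) -> float:
    """Compose one muscle's excitation from its delayed sensory signals.

    ``F_del``/``l_del``: the muscle's own normalized force and fiber length;
    ``theta_del``/``thetadot_del``: the PD feature wired to this (muscle,
    mode), already expressed in feature coordinates; ``F_sup_del``: the
    inhibition source's normalized force. ``load_share`` is the (delayed)
    fraction of body support borne by the leg: trunk-balance PD laws scale
    with it (the legs share the balance task through double support), and
    unload-gated constants scale with ``1 - load_share`` (the
    swing-initiation stim that builds as the trailing leg unloads).
    Result is clipped to [0, 1].
    """
    c = params.C[m, mode]
    if params.C_gate[m, mode] == 1:
        c *= max(1.0 - load_share, 0.0)
    u = params.u0[m] + c
    u += force_feedback(params.GF[m, mode], F_del)
    u += stretch_feedback(params.GL[m, mode], l_del, params.H[m, mode])
    if params.pd_feature[m, mode] != FEAT_NONE:
        s = params.pd_sign[m, mode]
        pd_scale = (load_share if params.pd_feature[m, mode] == FEAT_TRUNK
                    else 1.0)
        u += pd_scale * pd_feedback(params.KP[m, mode], params.KD[m, mode],
                                    s * theta_del, s * thetadot_del,
                                    s * params.theta_target[m, mode])
    if params.sup_source[m, mode] >= 0:
        u -= params.GS[m, mode] * F_sup_del
    if params.KG[m, mode] > 0.0 and qd_knee_del < 0.0:
        u -= params.KG[m, mode] * max(params.guard_angle - q_knee_del, 0.0)
    return min(max(u, 0.0), 1.0)


def compose_excitation(u0: float, law_outputs) -> float:
    """Baseline plus enabled law outputs, clipped to [0, 1]."""
    return min(max(u0 + float(np.sum(law_outputs)), 0.0), 1.0)


class ControlLayout:
    """Parsed wiring table: enumerates the free controller parameters.

    The flat parameter order is: law parameters in file order, shared PD
    targets, then d_swing. ``n_free`` must equal 56 for the nominal table.
    """

    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.guard_angle = float(cfg.get("knee_guard_angle", 0.25))
        self.delays_s = np.array(
            [cfg["delays_ms"][m] * 1e-3 for m in MUSCLES])
        self.slots: list[_Slot] = []
        self.bounds: list[tuple[float, float]] = []
        self.init: list[float] = []
        self._wiring: list[dict] = []   # static wiring applied to every decode
        self._target_slots: dict[str, list[tuple[int, int]]] = {}

        midx = {m: i for i, m in enumerate(MUSCLES)}
        modei = {m: i for i, m in enumerate(MODE_NAMES)}
        for law in cfg["laws"]:
            m = midx[law["muscle"]]
            mo = modei[law["mode"]]
            t = law["type"]
            if t == "force":
                self._add(law, "GF", m, mo, "G")
            elif t == "stretch":
                self._add(law, "GL", m, mo, "G")
                self._add(law, "H", m, mo, "H")
            elif t == "suppress":
                self._add(law, "GS", m, mo, "G")
                self._wiring.append(dict(array="sup_source", muscle=m,
                                         mode=mo, value=midx[law["source"]]))
            elif t == "pd":
                self._add(law, "KP", m, mo, "Kp")
                self._add(law, "KD", m, mo, "Kd")
                self._wiring.append(dict(array="pd_feature", muscle=m, mode=mo,
                                         value=_FEATURES[law["feature"]]))
                self._wiring.append(dict(array="pd_sign", muscle=m, mode=mo,
                                         value=float(law["sign"])))
                self._target_slots.setdefault(law["target"], []).append((m, mo))
            elif t == "knee_guard":
                self._add(law, "KG", m, mo, "K")
            elif t == "constant":
                self._add(law, "C", m, mo, "C")
                if law.get("gate") == "unload":
                    self._wiring.append(dict(array="C_gate", muscle=m,
                                             mode=mo, value=1))
            else:
                raise ValueError(f"unknown law type {t!r}")
        self._n_law_params = len(self.bounds)
        self.target_names = list(cfg.get("targets", {}))
        for name in self.target_names:
            spec = cfg["targets"][name]
            self.slots.append(_Slot("theta_target", -1, -1, f"target:{name}"))
            self.bounds.append(tuple(float(v) for v in spec["bounds"]))
            self.init.append(float(spec["init"]))
        ds = cfg["d_swing"]
        self.slots.append(_Slot("d_swing", -1, -1, "d_swing"))
        self.bounds.append(tuple(float(v) for v in ds["bounds"]))
        self.init.append(float(ds["init"]))

    def _add(self, law, array, m, mo, key):
        spec = law[key]
        self.slots.append(
            _Slot(array, m, mo, f"{law['mode']}:{law['muscle']}:{array}"))
        self.bounds.append(tuple(float(v) for v in spec["bounds"]))
        self.init.append(float(spec["init"]))

    @classmethod
    def from_yaml(cls, path=None) -> "ControlLayout":
        if path is None:
            text = (resources.files("reflexgait")
                    / "config/controller.yaml").read_text()
            cfg = yaml.safe_load(text)
        else:
            with open(path) as fh:
                cfg = yaml.safe_load(fh)
        return cls(cfg)

    @classmethod
    def default(cls) -> "ControlLayout":
        return cls.from_yaml()

    @property
    def n_free(self) -> int:
        return len(self.slots)

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    @property
    def init_vector(self) -> np.ndarray:
        return np.array(self.init)

    def labels(self) -> list[str]:
        return [s.label for s in self.slots]

    def decode(self, theta: np.ndarray,
               u0: np.ndarray | None = None) -> ControlParams:
        """Fill packed controller arrays from the flat parameter vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(
                f"expected {self.n_free} controller parameters, "
                f"got {theta.shape}")
        p = ControlParams.zeros(u0=u0, delays_s=self.delays_s,
                                guard_angle=self.guard_angle)
        for w in self._wiring:
            getattr(p, w["array"])[w["muscle"], w["mode"]] = w["value"]
        i = 0
        for slot in self.slots[:self._n_law_params]:
            getattr(p, slot.array)[slot.muscle, slot.mode] = theta[i]
            i += 1
        for name in self.target_names:
            for (m, mo) in self._target_slots.get(name, []):
                p.theta_target[m, mo] = theta[i]
            i += 1
        p.d_swing = float(theta[i])
        return p

    def encode(self, params: ControlParams) -> np.ndarray:
        """Flat parameter vector from packed arrays (inverse of decode)."""
        theta = np.empty(self.n_free)
        i = 0
        for slot in self.slots[:self._n_law_params]:
            theta[i] = getattr(params, slot.array)[slot.muscle, slot.mode]
            i += 1
        for name in self.target_names:
            m, mo = self._target_slots[name][0]
            theta[i] = params.theta_target[m, mo]
            i += 1
        theta[i] = params.d_swing
        return theta


class DelayBuffer:
    """Fixed-step ring buffer; queries at integer step delays are exact."""

    def __init__(self, n_channels: int, max_delay_steps: int,
                 initial: np.ndarray | None = None):
        self.n = max_delay_steps + 1
        self.buf = np.zeros((self.n, n_channels))
        if initial is not None:
            self.buf[:] = np.asarray(initial, dtype=float)
        self.head = 0

    def push(self, values: np.ndarray):
        self.head = (self.head + 1) % self.n
        self.buf[self.head] = values

    def delayed(self, delay_steps: int) -> np.ndarray:
        if not 0 <= delay_steps < self.n:
            raise ValueError("delay outside buffer capacity")
        return self.buf[(self.head - delay_steps) % self.n]
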