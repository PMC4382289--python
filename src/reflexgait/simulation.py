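"""Scenario construction and the closed-loop rollout engine.

A rollout integrates the coupled skeletal / muscle / reflex-controller
dynamics with a fixed-step semi-implicit Euler scheme at 0.1 ms. The fixed
step divides every sensory delay (5/10/20 ms) and the 100 Hz objective
sampling exactly, so delayed lookups are exact ring-buffer reads and results
are bitwise deterministic. Inclines are realized by rotating the gravity
vector while the contact plane stays at y = 0; reported kinematics therefore
live in the slope frame and forward velocity is measured along the slope.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from ._engine import njit
from .metabolics import MetabolicModel
from .model_core import SkeletonModel, ModelState
from .mtu import (MuscleSet, N_MUSCLES, force_length, force_velocity_inverse,
                  passive_force, tendon_force,
                  fiber_velocity_from_equilibrium)
from .reflex_control import ControlParams, GaitMode

DT_DEFAULT = 1e-4          # s; divides 5 ms delays and 10 ms sampling
RECORD_HZ = 100.0
FALL_HEIGHT_DEFAULT = 0.7  # m; vertical COM threshold defining a fall

GRAVITY_STD = 9.80665


@dataclass(frozen=True)
class Scenario:
    """Environment and task description for one optimization problem."""

    load_fraction: float = 0.0    # fraction of body mass carried on the back
    incline_deg: float = 0.0
    target_speed: float = 1.5     # m/s along the slope
    duration: float = 10.0        # s

    def __post_init__(self):
        if self.load_fraction < 0 or self.duration <= 0:
            raise ValueError("load_fraction >= 0 and duration > 0 required")

    @property
    def grade_percent(self) -> float:
        return 100.0 * np.tan(np.radians(self.incline_deg))


def attach_load(model: SkeletonModel, load_fraction: float) -> SkeletonModel:
    """Attach a backpack of ``load_fraction * body mass`` to the torso.

    The load is a point mass 0.1 m posterior to the torso COM with an own
    rotational inertia of 0.15 * M_back (kg m^2).
    """
    if not 0.0 <= load_fraction <= 1.0:
        raise ValueError("load_fraction must be in [0, 1]")
    if load_fraction == 0.0:
        return model
    m_back = load_fraction * model.body_mass
    return dataclasses.replace(
        model, extra_trunk_mass=m_back,
        extra_trunk_offset=np.array([-0.1, 0.0]),
        extra_trunk_inertia=0.15 * m_back, _arrays=None)


def apply_incline(model: SkeletonModel, incline_deg: float,
                  g: float = GRAVITY_STD) -> SkeletonModel:
    """Environment for walking up a slope of the given angle.

    Implemented by rotating the gravity vector in the slope frame (the
    contact plane stays at y = 0), which is dynamically equivalent to
    tilting the ground.
    """
    a = np.radians(incline_deg)
    return dataclasses.replace(
        model, gravity=np.array([-g * np.sin(a), -g * np.cos(a)]),
        _arrays=None)


def build_scenario_model(scenario: Scenario,
                         base: SkeletonModel | None = None) -> SkeletonModel:
    model = base if base is not None else SkeletonModel.default()
    model = attach_load(model, scenario.load_fraction)
    model = apply_incline(model, scenario.incline_deg)
    return model


# ----------------------------------------------------------- trajectories

@dataclass
class Trajectory:
    """Uniformly sampled record of one rollout (100 Hz channels).

    ``extras`` holds full-resolution channels (per integration step) used by
    event detection and impulse checks: gait modes, vertical GRF per leg and
    COM kinematics.
    """

    t: np.ndarray
    q: np.ndarray                # (n, 9)
    qd: np.ndarray               # (n, 9)
    excitations: np.ndarray      # (n, 16) right leg muscles first
    activations: np.ndarray      # (n, 16)
    fiber_length: np.ndarray     # (n, 16) normalized
    muscle_force: np.ndarray     # (n, 16) normalized by F_max
    joint_torques: np.ndarray    # (n, 6) muscle torques, joint convention
    limit_torques: np.ndarray    # (n, 6)
    hpe: np.ndarray              # (n,) squared joint-limit torque sum
    grf: np.ndarray              # (n, 4): [grf_x_r, grf_y_r, grf_x_l, grf_y_l]
    cop_x: np.ndarray            # (n, 2) per leg, nan when airborne
    gait_mode: np.ndarray        # (n, 2) int
    com: np.ndarray              # (n, 2)
    com_vel: np.ndarray          # (n, 2)
    head_vel: np.ndarray         # (n,) forward head velocity relative to COM
    metabolic_power: np.ndarray  # (n,) W, including basal rate
    fell: bool
    t_fall: float                # = duration when the model never fell
    duration: float
    body_mass: float
    back_mass: float
    extras: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.t)

    def heel_strikes(self, leg: str) -> np.ndarray:
        return self.extras["heel_strikes"][leg]

    def to_dataframe(self):
        import pandas as pd

        cols = {"time": self.t}
        for i, name in enumerate(
                ("trunk_x", "trunk_y", "trunk_pitch", "hip_r", "knee_r",
                 "ankle_r", "hip_l", "knee_l", "ankle_l")):
            cols[name] = self.q[:, i]
            cols[name + "_u"] = self.qd[:, i]
        for j, name in enumerate(("hip_r", "knee_r", "ankle_r", "hip_l",
                                  "knee_l", "ankle_l")):
            cols["tau_" + name] = self.joint_torques[:, j]
        for k, name in enumerate(("grf_x_r", "grf_y_r", "grf_x_l", "grf_y_l")):
            cols[name] = self.grf[:, k]
        from .mtu import MUSCLES
        for m, name in enumerate(MUSCLES):
            cols[f"F_{name}_r"] = self.muscle_force[:, m]
            cols[f"F_{name}_l"] = self.muscle_force[:, m + 8]
            cols[f"exc_{name}_r"] = self.excitations[:, m]
            cols[f"exc_{name}_l"] = self.excitations[:, m + 8]
        cols["com_x"] = self.com[:, 0]
        cols["com_y"] = self.com[:, 1]
        cols["metabolic_power"] = self.metabolic_power
        return pd.DataFrame(cols)

    def to_sto(self, path):
        """Write an OpenSim storage (.sto) dialect time-series file."""
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write("reflexgait trajectory\nversion=1\n"
                     f"nRows={len(df)}\nnColumns={len(df.columns)}\n"
                     "inDegrees=no\nendheader\n")
            fh.write("\t".join(df.columns) + "\n")
            np.savetxt(fh, df.to_numpy(), fmt="%.8g", delimiter="\t")

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def events_json(self, path=None):
        ev = {
            "fell": bool(self.fell),
            "t_fall": float(self.t_fall),
            "heel_strikes_r": [float(x) for x in self.heel_strikes("r")],
            "heel_strikes_l": [float(x) for x in self.heel_strikes("l")],
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(ev, fh, indent=1)
        return ev


def detect_heelstrikes(mode_series: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Times of swing -> stance transitions in a gait-mode series."""
    m = np.asarray(mode_series)
    idx = np.flatnonzero((m[1:] == int(GaitMode.STANCE))
                         & (m[:-1] != int(GaitMode.STANCE)))
    return t[idx + 1]


# ------------------------------------------------------------- the kernel

@njit(cache=True)
def _excite_kernel(u0, C, CG, GF, GL, H, GS, ssrc, KP, KD, TT, PDF, PDS, KG,
                   guard_angle, mode, F_del, l_del, th, thd, F_sup,
                   q_knee, qd_knee, load_share=1.0):
    c = C[mode]
    if CG[mode] == 1:
        unload = 1.0 - load_share
        c *= unload if unload > 0.0 else 0.0
    u = u0 + c
    u += GF[mode] * F_del
    x = l_del - H[mode]
    if x > 0.0:
        u += GL[mode] * x
    if PDF[mode] != 0:
        s = PDS[mode]
        p = KP[mode] * (s * th - s * TT[mode]) + KD[mode] * s * thd
        if p > 0.0:
            if PDF[mode] == 1:
                p *= load_share
            u += p
    if ssrc[mode] >= 0:
        u -= GS[mode] * F_sup
    if KG[mode] > 0.0 and qd_knee < 0.0:
        g = guard_angle - q_knee
        if g > 0.0:
            u -= KG[mode] * g
    if u < 0.0:
        return 0.0
    if u > 1.0:
        return 1.0
    return u


@njit(cache=True)
def _rollout_kernel(parent, jtype, jsign, joff, anchor, mass, inertia,
                    com_local, dof0, ndof, gx, gy,
                    lim_lo, lim_hi, lim_k, lim_c,
                    sph_body, sph_off, ck, cdiss, mu_s, mu_d, mu_v, v_t,
                    radius, on_thr, off_thr,
                    F_max, l_opt, v_maxn, slack, tau_act, u0m, n_arms,
                    arm_joint, arm_dir, arm_r0, arm_cos, arm_c, arm_qc, l_ref,
                    C, CGT, GF, GL, H, GS, ssrc, KP, KD, TT, PDF, PDS, KG,
                    guard_angle, delay_steps, d_swing,
                    w_am, short_coeff, basal_w,
                    q0, qd0, a0, lce0, dt, n_steps, rec_every, fall_height,
                    head_y_local):
    nm = 8
    nmu = 2 * nm
    q = q0.copy()
    qd = qd0.copy()
    act = a0.copy()
    lce = lce0.copy()

    n_rec = n_steps // rec_every + 1
    rec_t = np.zeros(n_rec)
    rec_q = np.zeros((n_rec, ndof))
    rec_qd = np.zeros((n_rec, ndof))
    rec_exc = np.zeros((n_rec, nmu))
    rec_act = np.zeros((n_rec, nmu))
    rec_lce = np.zeros((n_rec, nmu))
    rec_F = np.zeros((n_rec, nmu))
    rec_mtau = np.zeros((n_rec, 6))
    rec_ltau = np.zeros((n_rec, 6))
    rec_hpe = np.zeros(n_rec)
    rec_grf = np.zeros((n_rec, 4))
    rec_cop = np.full((n_rec, 2), np.nan)
    rec_mode = np.zeros((n_rec, 2), dtype=np.int64)
    rec_com = np.zeros((n_rec, 2))
    rec_comv = np.zeros((n_rec, 2))
    rec_head = np.zeros(n_rec)
    rec_met = np.zeros(n_rec)

    fr_mode = np.zeros((n_steps + 1, 2), dtype=np.int64)
    fr_grfy = np.zeros((n_steps + 1, 2))
    fr_comx = np.zeros(n_steps + 1)
    fr_comy = np.zeros(n_steps + 1)

    max_delay = 0
    for m in range(nm):
        if delay_steps[m] > max_delay:
            max_delay = delay_steps[m]
    nhist = max_delay + 1
    # history channels: F_norm(16), l_norm(16), lean, leand,
    # hip_r, hipd_r, knee_r, kneed_r, hip_l, hipd_l, knee_l, kneed_l,
    # load_share_r, load_share_l
    nchan = 2 * nmu + 12
    hist = np.zeros((nhist, nchan))
    head = 0

    in_contact = np.zeros(2, dtype=np.int64)
    mode = np.zeros(2, dtype=np.int64)
    exc = np.zeros(nmu)
    fell = False
    t_fall = n_steps * dt
    n_done = n_steps

    for step in range(n_steps + 1):
        t = step * dt
        # ---- state sanity: treat runaway/non-finite states as a fall
        # before they overflow downstream linear algebra
        bad = False
        for d in range(ndof):
            if not np.isfinite(q[d]) or not np.isfinite(qd[d]) \
                    or abs(qd[d]) > 1e4:
                bad = True
        if bad:
            fell = True
            t_fall = t
            n_done = step - 1 if step > 0 else 0
            break
        # ---- kinematics
        phi, w, p, vo = _engine.body_frames(parent, jtype, jsign, joff,
                                            anchor, dof0, q, qd)
        # ---- muscle geometry and forces
        F_norm = np.zeros(nmu)
        l_norm = np.zeros(nmu)
        v_ce = np.zeros(nmu)
        mtau = np.zeros(6)      # [hip_r, knee_r, ankle_r, hip_l, ...]
        for leg in range(2):
            qoff = 3 + 3 * leg
            for m in range(nm):
                i = m + nm * leg
                lmtu = l_ref[m]
                for s in range(n_arms[m]):
                    jq = q[qoff + arm_joint[m, s]]
                    if arm_cos[m, s] == 0:
                        lmtu += -arm_dir[m, s] * arm_r0[m, s] * jq
                    else:
                        lmtu += -arm_dir[m, s] * (arm_r0[m, s] / arm_c[m, s]) * (
                            np.sin(arm_c[m, s] * (jq - arm_qc[m, s]))
                            - np.sin(arm_c[m, s] * (-arm_qc[m, s])))
                fn, vce = fiber_velocity_from_equilibrium(
                    act[i], lce[i], lmtu, F_max[m], l_opt[m], v_maxn[m],
                    slack[m])
                F_norm[i] = fn
                v_ce[i] = vce
                l_norm[i] = lce[i] / l_opt[m]
                Fabs = fn * F_max[m]
                for s in range(n_arms[m]):
                    jloc = arm_joint[m, s]
                    jq = q[qoff + jloc]
                    if arm_cos[m, s] == 0:
                        r = arm_r0[m, s]
                    else:
                        r = arm_r0[m, s] * np.cos(arm_c[m, s] * (jq - arm_qc[m, s]))
                    mtau[3 * leg + jloc] += arm_dir[m, s] * r * Fabs

        # ---- joint limit torques
        ltau = np.zeros(6)
        hpe = 0.0
        for jj in range(6):
            d = 3 + jj
            if q[d] > lim_hi[d]:
                ltau[jj] = -lim_k[d] * (q[d] - lim_hi[d]) - lim_c[d] * qd[d]
            elif q[d] < lim_lo[d]:
                ltau[jj] = -lim_k[d] * (q[d] - lim_lo[d]) - lim_c[d] * qd[d]
            hpe += ltau[jj] * ltau[jj]

        # ---- contact
        Qc = np.zeros(ndof)
        grf = np.zeros(4)       # fx_r, fy_r, fx_l, fy_l
        copn = np.zeros(2)      # sum fy * x per leg
        for si in range(sph_body.shape[0]):
            b = sph_body[si]
            c = np.cos(phi[b])
            s = np.sin(phi[b])
            rx = c * sph_off[si, 0] - s * sph_off[si, 1]
            ry = s * sph_off[si, 0] + c * sph_off[si, 1]
            px = p[b, 0] + rx
            py = p[b, 1] + ry
            vx = vo[b, 0] - w[b] * ry
            vy = vo[b, 1] + w[b] * rx
            h = radius - py
            if h > 0.0:
                fn = ck * h ** 1.5 * (1.0 + 1.5 * cdiss * (-vy))
                if fn < 0.0:
                    fn = 0.0
            else:
                fn = 0.0
            if fn > 0.0:
                sv = abs(vx) / v_t
                if sv <= 1.0:
                    mu = mu_s * sv * sv * (3.0 - 2.0 * sv)
                elif sv <= 3.0:
                    uu = (sv - 1.0) / 2.0
                    mu = mu_s - (mu_s - mu_d) * uu * uu * (3.0 - 2.0 * uu)
                else:
                    mu = mu_d
                mu += mu_v * abs(vx)
                ft = -mu * fn if vx >= 0.0 else mu * fn
                leg = 0 if b == sph_body[0] else 1
                if b <= 3:
                    leg = 0
                else:
                    leg = 1
                grf[2 * leg] += ft
                grf[2 * leg + 1] += fn
                copn[leg] += fn * px
                # generalized forces along the chain
                i = b
                while i >= 0:
                    d = dof0[i]
                    if jtype[i] == 0:
                        Qc[d] += ft
                        Qc[d + 1] += fn
                        Qc[d + 2] += -(py - p[i, 1]) * ft + (px - p[i, 0]) * fn
                    else:
                        Qc[d] += jsign[i] * (
                            -(py - p[i, 1]) * ft + (px - p[i, 0]) * fn)
                    i = parent[i]

        # ---- contact state with hysteresis, gait modes
        cx, cy, cvx, cvy, mtot = _engine.com_state(parent, jtype, jsign, joff,
                                                   anchor, mass, com_local,
                                                   dof0, q, qd)
        for leg in range(2):
            fy = grf[2 * leg + 1]
            if step == 0:
                in_contact[leg] = 1 if fy > on_thr else 0
                mode[leg] = 0 if in_contact[leg] == 1 else 1
            else:
                if in_contact[leg] == 1:
                    if fy < off_thr:
                        in_contact[leg] = 0
                else:
                    if fy > on_thr:
                        in_contact[leg] = 1
            ankle_x = p[3 + 3 * leg, 0]
            if in_contact[leg] == 1:
                mode[leg] = 0
            elif mode[leg] == 0:
                mode[leg] = 1
            elif mode[leg] == 1 and (ankle_x - cx) > d_swing:
                mode[leg] = 2

        # ---- sensory history
        sig = np.zeros(nchan)
        for i in range(nmu):
            sig[i] = F_norm[i]
            sig[nmu + i] = l_norm[i]
        base = 2 * nmu
        sig[base] = -q[2]        # trunk forward lean
        sig[base + 1] = -qd[2]
        sig[base + 2] = q[3]
        sig[base + 3] = qd[3]
        sig[base + 4] = q[4]
        sig[base + 5] = qd[4]
        sig[base + 6] = q[6]
        sig[base + 7] = qd[6]
        sig[base + 8] = q[7]
        sig[base + 9] = qd[7]
        # fraction of total support borne by each leg (trunk-PD gate)
        fy_tot = grf[1] + grf[3]
        if fy_tot > 1.0:
            sig[base + 10] = grf[1] / fy_tot
            sig[base + 11] = grf[3] / fy_tot
        else:
            sig[base + 10] = 0.0
            sig[base + 11] = 0.0
        if step == 0:
            for r0 in range(nhist):
                hist[r0] = sig
        else:
            head = (head + 1) % nhist
            hist[head] = sig

        # ---- excitations from delayed signals
        for leg in range(2):
            for m in range(nm):
                i = m + nm * leg
                row = hist[(head - delay_steps[m]) % nhist]
                feat = PDF[m, mode[leg]]
                th = 0.0
                thd = 0.0
                load_share = row[base + 10 + leg]
                if feat == 1:
                    th = row[base]
                    thd = row[base + 1]
                elif feat == 2:
                    th = row[base + 2 + 4 * leg]
                    thd = row[base + 3 + 4 * leg]
                elif feat == 3:
                    th = row[base + 4 + 4 * leg]
                    thd = row[base + 5 + 4 * leg]
                fs = 0.0
                if ssrc[m, mode[leg]] >= 0:
                    fs = row[ssrc[m, mode[leg]] + nm * leg]
                exc[i] = _excite_kernel(
                    u0m[m], C[m], CGT[m], GF[m], GL[m], H[m], GS[m], ssrc[m],
                    KP[m], KD[m], TT[m], PDF[m], PDS[m], KG[m], guard_angle,
                    mode[leg], row[i], row[nmu + i], th, thd, fs,
                    row[base + 4 + 4 * leg], row[base + 5 + 4 * leg],
                    load_share)

        # ---- metabolic power
        met = basal_w
        for leg in range(2):
            for m in range(nm):
                i = m + nm * leg
                met += w_am[m] * act[i]
                sp = -F_norm[i] * F_max[m] * v_ce[i]
                if sp > 0.0:
                    met += (1.0 + short_coeff) * sp

        # ---- head velocity relative to COM (forward)
        hc = np.cos(phi[0])
        hs = np.sin(phi[0])
        hrx = -hs * head_y_local
        hry = hc * head_y_local
        head_vx = vo[0, 0] - w[0] * hry
        head_rel = head_vx - cvx

        # ---- record
        fr_mode[step, 0] = mode[0]
        fr_mode[step, 1] = mode[1]
        fr_grfy[step, 0] = grf[1]
        fr_grfy[step, 1] = grf[3]
        fr_comx[step] = cx
        fr_comy[step] = cy
        if step % rec_every == 0:
            r = step // rec_every
            rec_t[r] = t
            for d in range(ndof):
                rec_q[r, d] = q[d]
                rec_qd[r, d] = qd[d]
            for i in range(nmu):
                rec_exc[r, i] = exc[i]
                rec_act[r, i] = act[i]
                rec_lce[r, i] = l_norm[i]
                rec_F[r, i] = F_norm[i]
            for jj in range(6):
                rec_mtau[r, jj] = mtau[jj]
                rec_ltau[r, jj] = ltau[jj]
            rec_hpe[r] = hpe
            for k4 in range(4):
                rec_grf[r, k4] = grf[k4]
            for leg in range(2):
                if grf[2 * leg + 1] > 0.0:
                    rec_cop[r, leg] = copn[leg] / grf[2 * leg + 1]
                rec_mode[r, leg] = mode[leg]
            rec_com[r, 0] = cx
            rec_com[r, 1] = cy
            rec_comv[r, 0] = cvx
            rec_comv[r, 1] = cvy
            rec_head[r] = head_rel
            rec_met[r] = met

        # ---- fall check
        if cy < fall_height:
            fell = True
            t_fall = t
            n_done = step
            break
        if step == n_steps:
            break

        # ---- integrate
        Q = Qc
        for jj in range(6):
            Q[3 + jj] += mtau[jj] + ltau[jj]
        M = _engine.mass_matrix(parent, jtype, jsign, joff, anchor, mass,
                                inertia, com_local, dof0, ndof, q)
        bias = _engine.bias_forces(parent, jtype, jsign, joff, anchor, mass,
                                   inertia, com_local, dof0, ndof, q, qd,
                                   gx, gy)
        qdd = np.linalg.solve(M, Q - bias)
        ok = True
        for d in range(ndof):
            if not np.isfinite(qdd[d]):
                ok = False
        if not ok:
            fell = True
            t_fall = t
            n_done = step
            break
        for d in range(ndof):
            qd[d] += dt * qdd[d]
            q[d] += dt * qd[d]
        for leg in range(2):
            for m in range(nm):
                i = m + nm * leg
                u = exc[i]
                act[i] = u + (act[i] - u) * np.exp(-dt / tau_act[m])
                lce[i] += dt * v_ce[i]

    n_rec_done = n_done // rec_every + 1
    return (rec_t[:n_rec_done], rec_q[:n_rec_done], rec_qd[:n_rec_done],
            rec_exc[:n_rec_done], rec_act[:n_rec_done], rec_lce[:n_rec_done],
            rec_F[:n_rec_done], rec_mtau[:n_rec_done], rec_ltau[:n_rec_done],
            rec_hpe[:n_rec_done], rec_grf[:n_rec_done], rec_cop[:n_rec_done],
            rec_mode[:n_rec_done], rec_com[:n_rec_done],
            rec_comv[:n_rec_done], rec_head[:n_rec_done], rec_met[:n_rec_done],
            fr_mode[:n_done + 1], fr_grfy[:n_done + 1], fr_comx[:n_done + 1],
            fr_comy[:n_done + 1], fell, t_fall, n_done)


# ------------------------------------------------------------- public API

def initial_muscle_state(model: SkeletonModel, muscles: MuscleSet,
                         q: np.ndarray):
    """Baseline activations and near-equilibrium initial fiber lengths."""
    from .mtu import MUSCLES

    a0 = np.empty(2 * N_MUSCLES)
    lce0 = np.empty(2 * N_MUSCLES)
    for leg in range(2):
        q_leg = q[3 + 3 * leg: 6 + 3 * leg]
        for m, name in enumerate(MUSCLES):
            p = muscles[name]
            i = m + N_MUSCLES * leg
            a0[i] = p.u0
            lmtu = muscles.path_length(name, q_leg)
            lce0[i] = min(max(lmtu - p.tendon_slack, 0.6 * p.l_opt),
                          1.4 * p.l_opt)
    return a0, lce0


def rollout(model: SkeletonModel, control_params: ControlParams,
            initial_conditions: np.ndarray,
            scenario: Scenario | None = None,
            muscles: MuscleSet | None = None,
            metabolic_model: MetabolicModel | None = None,
            dt: float = DT_DEFAULT,
            fall_height: float = FALL_HEIGHT_DEFAULT) -> Trajectory:
    """Integrate the full closed loop for the scenario duration (or until a
    fall) and return the recorded :class:`Trajectory`.

    ``initial_conditions`` is the 18-vector [q(9), qdot(9)]. The model
    passed in should already carry the scenario's load and incline (see
    :func:`build_scenario_model`).
    """
    if scenario is None:
        scenario = Scenario()
    if muscles is None:
        muscles = MuscleSet.default()
    if metabolic_model is None:
        metabolic_model = MetabolicModel()
    ic = np.asarray(initial_conditions, dtype=float)
    if ic.shape != (18,):
        raise ValueError("expected 18 initial conditions (9 q + 9 qdot)")
    q0 = ic[:9].copy()
    qd0 = ic[9:].copy()

    arr = model.arrays()
    lim_lo, lim_hi, lim_k, lim_c = model.limit_arrays()
    sph_body, sph_off = model.sphere_arrays()
    pk = muscles.packed()
    cp = control_params
    c = model.contact

    a0, lce0 = initial_muscle_state(model, muscles, q0)
    mm = metabolic_model
    w_am = mm.activation_rate * mm.muscle_mass(pk["F_max"], pk["l_opt"])
    basal_w = mm.basal_rate * model.body_mass

    n_steps = int(round(scenario.duration / dt))
    rec_every = int(round(1.0 / (RECORD_HZ * dt)))
    delay_steps = np.round(cp.delays_s / dt).astype(np.int64)

    out = _rollout_kernel(
        *arr.full, model.gravity[0], model.gravity[1],
        lim_lo, lim_hi, lim_k, lim_c,
        sph_body, sph_off, c.k, c.c, c.mu_s, c.mu_d, c.mu_v, c.v_t,
        c.sphere_radius, c.on_threshold, c.off_threshold,
        pk["F_max"], pk["l_opt"], pk["v_max"], pk["slack"], pk["tau"],
        pk["u0"], pk["n_arms"], pk["arm_joint"], pk["arm_dir"], pk["arm_r0"],
        pk["arm_cos"], pk["arm_c"], pk["arm_qc"], pk["l_ref"],
        cp.C, cp.C_gate, cp.GF, cp.GL, cp.H, cp.GS, cp.sup_source, cp.KP,
        cp.KD, cp.theta_target, cp.pd_feature, cp.pd_sign, cp.KG,
        cp.guard_angle,
        delay_steps, cp.d_swing,
        w_am, mm.shortening_coeff, basal_w,
        q0, qd0, a0, lce0, dt, n_steps, rec_every, fall_height,
        model.head_local[1])

    (rec_t, rec_q, rec_qd, rec_exc, rec_act, rec_lce, rec_F, rec_mtau,
     rec_ltau, rec_hpe, rec_grf, rec_cop, rec_mode, rec_com, rec_comv,
     rec_head, rec_met, fr_mode, fr_grfy, fr_comx, fr_comy, fell, t_fall,
     n_done) = out

    fr_t = np.arange(n_done + 1) * dt
    heel = {leg: detect_heelstrikes(fr_mode[:, li], fr_t)
            for li, leg in enumerate(("r", "l"))}
    return Trajectory(
        t=rec_t, q=rec_q, qd=rec_qd, excitations=rec_exc, activations=rec_act,
        fiber_length=rec_lce, muscle_force=rec_F, joint_torques=rec_mtau,
        limit_torques=rec_ltau, hpe=rec_hpe, grf=rec_grf, cop_x=rec_cop,
        gait_mode=rec_mode, com=rec_com, com_vel=rec_comv, head_vel=rec_head,
        metabolic_power=rec_met, fell=bool(fell), t_fall=float(t_fall),
        duration=scenario.duration, body_mass=model.body_mass,
        back_mass=model.extra_trunk_mass,
        extras=dict(dt=dt, fr_t=fr_t, fr_mode=fr_mode, fr_grfy=fr_grfy,
                    fr_comx=fr_comx, fr_comy=fr_comy, heel_strikes=heel))


def passive_settle(tree, contact_params, q0, qd0, gravity, spheres,
                   duration=1.0, dt=DT_DEFAULT, ground_angle=0.0,
                   record_q=False):
    """Integrate a passive tree with sphere contact (test/diagnostic helper).

    ``spheres``: list of (body_index, local_offset). Returns final state and
    the plane-normal GRF time series (optionally the coordinate history).
    """
    from .contact import sphere_contact

    q = np.asarray(q0, dtype=float).copy()
    qd = np.asarray(qd0, dtype=float).copy()
    n = int(round(duration / dt))
    grf_y = np.zeros(n)
    qs = np.zeros((n, tree.ndof)) if record_q else None
    for s in range(n):
        phi, w, p, vo = _engine.body_frames(*tree.tree, tree.dof0, q, qd)
        Q = np.zeros(tree.ndof)
        fy_tot = 0.0
        for b, off in spheres:
            px, py, vx, vy = _engine.point_state(*tree.tree, tree.dof0, q, qd,
                                                 b, off[0], off[1])
            fn, ft, _, fw = sphere_contact(px, py, vx, vy, contact_params,
                                           ground_angle=ground_angle)
            if fn > 0.0:
                J = _engine.point_jacobian(*tree.tree, tree.dof0, tree.ndof,
                                           phi, p, b, px, py)
                Q += J.T @ np.array(fw)
                fy_tot += fn
        grf_y[s] = fy_tot
        qdd = _engine.forward_dynamics_core(*tree.full, q, qd, Q,
                                            gravity[0], gravity[1])
        qd += dt * qdd
        q += dt * qd
        if record_q:
            qs[s] = q
    if record_q:
        return q, qd, grf_y, qs
    return q, qd, grf_y
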