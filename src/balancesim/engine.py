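"""Compiled fixed-step forward-dynamics kernel.

The plant is a 9-DOF planar kinematic tree (floating pelvis+torso, bilateral
thigh/shank/foot).  Each step evaluates muscle geometry and Hill forces,
foot-platform contact, the three delayed feedback laws, and advances the
body coordinates with semi-implicit (symplectic) Euler.  Joint-space
dynamics use the composite-rigid-body algorithm for the mass matrix and a
recursive Newton-Euler pass for velocity/gravity bias, both expressed in
world-frame planar spatial coordinates.  The platform slider is
kinematically prescribed to the commanded sinusoid, so it contributes
through contact only.

Everything here operates on packed flat arrays; the object layer in
``msk_model``/``control`` builds them.  The kernel is deterministic: no
randomness, fixed iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .muscle import (FL_WIDTH, FV_CON_K, FV_ECC_C, FV_ECC_MAX, FP_CAP,
                     FP_SHAPE, FP_STRAIN, UNIQUE_MUSCLES)

FP_DENOM = math.exp(FP_SHAPE) - 1.0

NB = 9   # dynamic bodies: base-x, base-y, HAT, 2x(thigh, shank, foot)
NM = 18
NC = 4

#: engine generalized-coordinate order (equals SimState.q[1:])
ENGINE_COORDS = ("pelvis_tx", "pelvis_ty", "pelvis_tilt",
                 "hip_r", "knee_r", "ankle_r", "hip_l", "knee_l", "ankle_l")


@dataclass
class PackedModel:
    parent: np.ndarray
    jtype: np.ndarray      # 0 prismatic-x, 1 prismatic-y, 2 revolute
    jsign: np.ndarray
    jloc: np.ndarray       # (NB, 2) joint anchor in parent frame
    mass: np.ndarray
    inertia: np.ndarray
    comloc: np.ndarray     # (NB, 2) COM in body frame
    sbody: np.ndarray      # contact sphere body indices
    sloc: np.ndarray
    srad: np.ndarray
    contact: np.ndarray    # k, c, mu_s, mu_d, mu_v, v_t
    fmax: np.ndarray
    lopt: np.ndarray
    marm: np.ndarray       # (NM, NB), flexion-positive moment arms
    tdm: np.ndarray        # (NM,) reflex delays s
    vmax_rel: float
    tau_act: float
    tau_deact: float
    qref: np.ndarray       # (NB,) muscle-length reference angles
    gravity: float
    locked: np.ndarray = None  # indices of pinned coordinates
    qmin: np.ndarray = None    # (NB,) passive ROM lower bounds, rad
    qmax: np.ndarray = None
    klim: float = 0.0          # limit-stop stiffness, N m / rad
    dlim: float = 0.0          # limit-stop damping, N m s / rad


def pack_model(model) -> PackedModel:
    hat = model.segment("hat")
    thigh = model.segment("thigh_r")
    shank = model.segment("shank_r")
    foot = model.segment("foot_r")
    fg = model.foot_geometry

    parent = np.array([-1, 0, 1, 2, 3, 4, 2, 6, 7], dtype=np.int64)
    jtype = np.array([0, 1, 2, 2, 2, 2, 2, 2, 2], dtype=np.int64)
    jsign = np.array([1.0, 1.0, -1.0, 1.0, -1.0, 1.0, 1.0, -1.0, 1.0])
    jloc = np.zeros((NB, 2))
    jloc[4] = jloc[7] = (0.0, -thigh.length)   # knee anchor in thigh frame
    jloc[5] = jloc[8] = (0.0, -shank.length)   # ankle anchor in shank frame

    mass = np.zeros(NB)
    inertia = np.zeros(NB)
    comloc = np.zeros((NB, 2))
    foot_com = (foot.com_offset - fg["heel_back"], -0.5 * fg["ankle_height"])
    for idx, seg, com in ((2, hat, (0.0, hat.com_offset)),
                          (3, thigh, (0.0, -thigh.com_offset)),
                          (4, shank, (0.0, -shank.com_offset)),
                          (5, foot, foot_com),
                          (6, thigh, (0.0, -thigh.com_offset)),
                          (7, shank, (0.0, -shank.com_offset)),
                          (8, foot, foot_com)):
        mass[idx] = seg.mass
        inertia[idx] = seg.moment_of_inertia
        comloc[idx] = com

    body_index = {"foot_r": 5, "foot_l": 8}
    sbody = np.array([body_index[s.segment] for s in model.contact_spheres],
                     dtype=np.int64).reshape(-1)
    sloc = np.array([s.local_offset for s in model.contact_spheres],
                    dtype=float).reshape(-1, 2)
    srad = np.array([s.radius for s in model.contact_spheres],
                    dtype=float).reshape(-1)
    cp = model.contact_params
    contact = np.array([cp.stiffness, cp.dissipation, cp.mu_static,
                        cp.mu_dynamic, cp.mu_viscous, cp.transition_velocity])

    coord_col = {name: i for i, name in enumerate(ENGINE_COORDS)}
    fmaxv = np.zeros(NM)
    loptv = np.zeros(NM)
    marm = np.zeros((NM, NB))
    tdm = np.zeros(NM)
    for i, m in enumerate(model.muscles):
        fmaxv[i] = m.f_max
        loptv[i] = m.l_opt
        tdm[i] = m.reflex_delay
        for joint, r in m.moment_arms.items():
            marm[i, coord_col[joint]] = r

    from .msk_model import muscle_reference_angles
    ref = muscle_reference_angles(model)
    qref = np.zeros(NB)
    for name, val in ref.items():
        qref[coord_col[name]] = val
    md = model.muscle_dynamics
    locked = np.array([ENGINE_COORDS.index(c) for c in model.locked_coords],
                      dtype=np.int64).reshape(-1)
    qmin = np.full(NB, -np.inf)
    qmax = np.full(NB, np.inf)
    jl = model.joint_limits or {}
    for joint, cols in (("hip", (3, 6)), ("knee", (4, 7)), ("ankle", (5, 8))):
        if joint in jl:
            lo_deg, hi_deg = jl[joint]
            for c in cols:
                qmin[c] = math.radians(lo_deg)
                qmax[c] = math.radians(hi_deg)
    return PackedModel(parent, jtype, jsign, jloc, mass, inertia, comloc,
                       sbody, sloc, srad, contact, fmaxv, loptv, marm, tdm,
                       float(md.get("v_max", 10.0)),
                       float(md.get("tau_act", 0.010)),
                       float(md.get("tau_deact", 0.040)),
                       qref, model.gravity, locked, qmin, qmax,
                       float(jl.get("stiffness", 0.0)),
                       float(jl.get("damping", 0.0)))


# ---------------------------------------------------------------------------
# compiled kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _rollout(parent, jtype, jsign, jloc, mass, inertia, comloc,
             sbody, sloc, srad, contact,
             fmax, lopt, marm, vmax_rel, tau_a, tau_d, qref, grav, locked,
             qmin, qmax, klim, dlim,
             q_in, qd_in, a_in,
             KL, L0, G, KCP, KCV, dm_steps, dcom_steps, ubase,
             use_controller, exc_fixed,
             amp, freq, t0, dt, nsteps,
             fall_frac, knee_lim, tilt_lim, tran_lim, pen_val,
             record,
             rec_q, rec_qd, rec_act, rec_exc, rec_F,
             rec_cn, rec_ct, rec_com, rec_comv, rec_fcom,
             rec_cop, rec_plat, rec_grf):
    nb = parent.shape[0]
    nm = fmax.shape[0]
    nc = sbody.shape[0]

    q = q_in.copy()
    qd = qd_in.copy()
    act = a_in.copy()

    k_c = contact[0]; c_diss = contact[1]
    mu_s = contact[2]; mu_d = contact[3]; mu_v = contact[4]; v_t = contact[5]

    # kinematic scratch
    phi = np.zeros(nb); omg = np.zeros(nb)
    o = np.zeros((nb, 2)); vo = np.zeros((nb, 2))
    axw = np.zeros((nb, 2))
    cw = np.zeros((nb, 2)); vc = np.zeros((nb, 2))
    S = np.zeros((nb, 3))
    Ic = np.zeros((nb, 3, 3))
    M = np.zeros((nb, nb))
    alph = np.zeros(nb); ao = np.zeros((nb, 2))
    fb = np.zeros((nb, 2)); nb_t = np.zeros(nb)
    tau = np.zeros(nb)
    lnorm = np.zeros(nm); vnorm = np.zeros(nm); F = np.zeros(nm)
    rhs = np.empty(nb)
    exc = np.zeros(nm)
    cn = np.zeros(nc); ct = np.zeros(nc); cpx = np.zeros(nc)

    # delay buffers
    lbuf = np.zeros((nsteps + 1, nm))
    fbuf = np.zeros((nsteps + 1, nm))
    dpbuf = np.zeros(nsteps + 1)
    dvbuf = np.zeros(nsteps + 1)

    mtot = 0.0
    for i in range(nb):
        mtot += mass[i]
    mfeet = mass[5] + mass[8]

    com_y0 = 0.0
    q0_tx = q[0]
    effort = 0.0
    dofint = 0.0
    prev_sumsq = 0.0
    prev_pen = 0.0
    t_term = nsteps * dt
    fell = 0
    rows = 0
    w2pi = 2.0 * math.pi * freq

    for k in range(nsteps + 1):
        t = k * dt
        xplat = amp * math.sin(w2pi * (t0 + t))
        vplat = amp * w2pi * math.cos(w2pi * (t0 + t))

        # ---- forward kinematics (alpha = jsign * q) -----------------------
        for i in range(nb):
            p = parent[i]
            if p < 0:
                php = 0.0; wp = 0.0
                opx = 0.0; opy = 0.0; vpx = 0.0; vpy = 0.0
            else:
                php = phi[p]; wp = omg[p]
                opx = o[p, 0]; opy = o[p, 1]
                vpx = vo[p, 0]; vpy = vo[p, 1]
            cp_ = math.cos(php); sp_ = math.sin(php)
            ai = jsign[i] * q[i]
            adi = jsign[i] * qd[i]
            if jtype[i] == 2:
                rx = cp_ * jloc[i, 0] - sp_ * jloc[i, 1]
                ry = sp_ * jloc[i, 0] + cp_ * jloc[i, 1]
                phi[i] = php + ai
                omg[i] = wp + adi
                o[i, 0] = opx + rx
                o[i, 1] = opy + ry
                vo[i, 0] = vpx - wp * ry
                vo[i, 1] = vpy + wp * rx
                axw[i, 0] = 0.0; axw[i, 1] = 0.0
            else:
                if jtype[i] == 0:
                    alx = 1.0; aly = 0.0
                else:
                    alx = 0.0; aly = 1.0
                awx = cp_ * alx - sp_ * aly
                awy = sp_ * alx + cp_ * aly
                lx = jloc[i, 0] + ai * alx
                ly = jloc[i, 1] + ai * aly
                rx = cp_ * lx - sp_ * ly
                ry = sp_ * lx + cp_ * ly
                phi[i] = php
                omg[i] = wp
                o[i, 0] = opx + rx
                o[i, 1] = opy + ry
                vo[i, 0] = vpx - wp * ry + adi * awx
                vo[i, 1] = vpy + wp * rx + adi * awy
                axw[i, 0] = awx; axw[i, 1] = awy
            ci = math.cos(phi[i]); si = math.sin(phi[i])
            rcx = ci * comloc[i, 0] - si * comloc[i, 1]
            rcy = si * comloc[i, 0] + ci * comloc[i, 1]
            cw[i, 0] = o[i, 0] + rcx
            cw[i, 1] = o[i, 1] + rcy
            vc[i, 0] = vo[i, 0] - omg[i] * rcy
            vc[i, 1] = vo[i, 1] + omg[i] * rcx

        # ---- whole-body and feet COM -------------------------------------
        comx = 0.0; comy = 0.0; comvx = 0.0; comvy = 0.0
        for i in range(nb):
            comx += mass[i] * cw[i, 0]; comy += mass[i] * cw[i, 1]
            comvx += mass[i] * vc[i, 0]; comvy += mass[i] * vc[i, 1]
        comx /= mtot; comy /= mtot; comvx /= mtot; comvy /= mtot
        fcomx = (mass[5] * cw[5, 0] + mass[8] * cw[8, 0]) / mfeet
        fcomvx = (mass[5] * vc[5, 0] + mass[8] * vc[8, 0]) / mfeet
        if k == 0:
            com_y0 = comy

        # ---- muscle geometry and force -----------------------------------
        for m in range(nm):
            dl = 0.0; dv = 0.0
            for j in range(3, nb):
                r = marm[m, j]
                if r != 0.0:
                    dl -= r * (q[j] - qref[j])
                    dv -= r * qd[j]
            ln = 1.0 + dl / lopt[m]
            if ln < 0.05:
                ln = 0.05
            vn = dv / (lopt[m] * vmax_rel)
            lnorm[m] = ln
            vnorm[m] = vn
            x = (ln - 1.0) / FL_WIDTH
            fl = math.exp(-x * x)
            v = vn
            if v < -1.0:
                v = -1.0
            if v > 1.0:
                v = 1.0
            if v <= 0.0:
                fv = (1.0 + v) / (1.0 - v / FV_CON_K)
            else:
                fv = (FV_ECC_MAX * v + FV_ECC_C) / (v + FV_ECC_C)
            if ln > 1.0:
                fp = (math.exp(FP_SHAPE * (ln - 1.0) / FP_STRAIN) - 1.0) \
                    / FP_DENOM
                if fp > FP_CAP:
                    fp = FP_CAP
            else:
                fp = 0.0
            f = fmax[m] * (act[m] * fl * fv + fp)
            if f < 0.0:
                f = 0.0
            F[m] = f
            lbuf[k, m] = ln
            fbuf[k, m] = f / fmax[m]

        dpbuf[k] = fcomx - comx
        dvbuf[k] = fcomvx - comvx

        # ---- contact -------------------------------------------------------
        fn_tot = 0.0
        ft_tot = 0.0
        cop_num = 0.0
        for s in range(nc):
            b = sbody[s]
            cb = math.cos(phi[b]); sb = math.sin(phi[b])
            rx = cb * sloc[s, 0] - sb * sloc[s, 1]
            ry = sb * sloc[s, 0] + cb * sloc[s, 1]
            pcx = o[b, 0] + rx
            pcy = o[b, 1] + ry
            vpcx = vo[b, 0] - omg[b] * ry
            vpcy = vo[b, 1] + omg[b] * rx
            depth = srad[s] - pcy
            if depth > 0.0:
                fn = k_c * depth ** 1.5 * (1.0 + 1.5 * c_diss * (-vpcy))
                if fn < 0.0:
                    fn = 0.0
            else:
                fn = 0.0
            ftan = 0.0
            if fn > 0.0:
                slip = vpcx - vplat
                sv = abs(slip) / v_t
                mu = math.tanh(3.0 * sv) * (mu_d + (mu_s - mu_d)
                                            * math.exp(-(sv - 1.0) ** 2)) \
                    + mu_v * abs(slip)
                if slip > 0.0:
                    ftan = -mu * fn
                else:
                    ftan = mu * fn
            cn[s] = fn
            ct[s] = ftan
            cpx[s] = pcx
            fn_tot += fn
            ft_tot += ftan
            cop_num += fn * pcx

        # ---- record -------------------------------------------------------
        if record:
            for j in range(nb):
                rec_q[k, j] = q[j]
                rec_qd[k, j] = qd[j]
            for m in range(nm):
                rec_act[k, m] = act[m]
                rec_F[k, m] = F[m]
            for s in range(nc):
                rec_cn[k, s] = cn[s]
                rec_ct[k, s] = ct[s]
            rec_com[k, 0] = comx; rec_com[k, 1] = comy
            rec_comv[k, 0] = comvx; rec_comv[k, 1] = comvy
            rec_fcom[k, 0] = fcomx; rec_fcom[k, 1] = fcomvx
            rec_cop[k] = cop_num / fn_tot if fn_tot > 0.0 else np.nan
            rec_plat[k, 0] = xplat; rec_plat[k, 1] = vplat
            rec_grf[k, 0] = ft_tot; rec_grf[k, 1] = fn_tot
        rows = k + 1

        # ---- objective accumulators (trapezoid) ---------------------------
        sumsq = 0.0
        for m in range(nm):
            sumsq += act[m] * act[m]
        pen = 0.0
        if q[4] > knee_lim or q[7] > knee_lim:
            pen += pen_val
        if abs(q[2]) > tilt_lim:
            pen += pen_val
        if abs(q[0] - q0_tx) > tran_lim:
            pen += pen_val
        if k > 0:
            effort += 0.5 * (prev_sumsq + sumsq) * dt
            dofint += 0.5 * (prev_pen + pen) * dt
        prev_sumsq = sumsq
        prev_pen = pen

        # ---- fall / divergence check --------------------------------------
        diverged = not math.isfinite(comy) or abs(comy) > 100.0
        for i in range(nb):
            if not (math.isfinite(q[i]) and math.isfinite(qd[i])) \
                    or abs(q[i]) > 1e4 or abs(qd[i]) > 1e4:
                diverged = True
        if diverged or comy < fall_frac * com_y0:
            t_term = t
            fell = 1
            break

        # ---- excitations --------------------------------------------------
        if use_controller:
            jc = k - dcom_steps
            if jc < 0:
                jc = 0
            dp = dpbuf[jc]
            dv = dvbuf[jc]
            for m in range(nm):
                jm = k - dm_steps[m]
                if jm < 0:
                    jm = 0
                u = KL[m] * (lbuf[jm, m] - L0[m])
                for src in range(nm):
                    g = G[m, src]
                    if g != 0.0:
                        u += g * fbuf[jm, src]
                u += KCP[m] * dp + KCV[m] * dv + ubase
                if u < 0.0:
                    u = 0.0
                if u > 1.0:
                    u = 1.0
                exc[m] = u
        else:
            for m in range(nm):
                exc[m] = exc_fixed[m]
        if record:
            for m in range(nm):
                rec_exc[k, m] = exc[m]
        if k == nsteps:
            break

        # ---- activation dynamics ------------------------------------------
        for m in range(nm):
            if exc[m] >= act[m]:
                tau_m = tau_a
            else:
                tau_m = tau_d
            a_new = act[m] + dt * (exc[m] - act[m]) / tau_m
            if a_new < 0.0:
                a_new = 0.0
            if a_new > 1.0:
                a_new = 1.0
            act[m] = a_new

        # ---- generalized forces -------------------------------------------
        for j in range(nb):
            tq = 0.0
            for m in range(nm):
                r = marm[m, j]
                if r != 0.0:
                    tq += r * F[m]
            # passive range-of-motion stop (flexion-positive convention)
            if klim > 0.0:
                if q[j] < qmin[j]:
                    tq += klim * (qmin[j] - q[j]) - dlim * qd[j]
                elif q[j] > qmax[j]:
                    tq += klim * (qmax[j] - q[j]) - dlim * qd[j]
            tau[j] = jsign[j] * tq
        # contact wrench -> generalized forces via point Jacobians
        for s in range(nc):
            if cn[s] > 0.0 or ct[s] != 0.0:
                b = sbody[s]
                cb = math.cos(phi[b]); sb = math.sin(phi[b])
                px = o[b, 0] + cb * sloc[s, 0] - sb * sloc[s, 1]
                py = o[b, 1] + sb * sloc[s, 0] + cb * sloc[s, 1] - srad[s]
                Fx = ct[s]; Fy = cn[s]
                j = b
                while j >= 0:
                    if jtype[j] == 2:
                        tau[j] += (px - o[j, 0]) * Fy - (py - o[j, 1]) * Fx
                    else:
                        tau[j] += axw[j, 0] * Fx + axw[j, 1] * Fy
                    j = parent[j]

        # ---- mass matrix (CRBA, world planar coordinates) -----------------
        for i in range(nb):
            if jtype[i] == 2:
                S[i, 0] = 1.0; S[i, 1] = o[i, 1]; S[i, 2] = -o[i, 0]
            else:
                S[i, 0] = 0.0; S[i, 1] = axw[i, 0]; S[i, 2] = axw[i, 1]
            m_ = mass[i]
            cx = cw[i, 0]; cy = cw[i, 1]
            Ic[i, 0, 0] = inertia[i] + m_ * (cx * cx + cy * cy)
            Ic[i, 0, 1] = -m_ * cy; Ic[i, 0, 2] = m_ * cx
            Ic[i, 1, 0] = -m_ * cy; Ic[i, 1, 1] = m_; Ic[i, 1, 2] = 0.0
            Ic[i, 2, 0] = m_ * cx; Ic[i, 2, 1] = 0.0; Ic[i, 2, 2] = m_
        for i in range(nb):
            for a_ in range(nb):
                M[i, a_] = 0.0
        for i in range(nb - 1, -1, -1):
            p = parent[i]
            if p >= 0:
                for r_ in range(3):
                    for c_ in range(3):
                        Ic[p, r_, c_] += Ic[i, r_, c_]
            f0 = Ic[i, 0, 0] * S[i, 0] + Ic[i, 0, 1] * S[i, 1] + Ic[i, 0, 2] * S[i, 2]
            f1 = Ic[i, 1, 0] * S[i, 0] + Ic[i, 1, 1] * S[i, 1] + Ic[i, 1, 2] * S[i, 2]
            f2 = Ic[i, 2, 0] * S[i, 0] + Ic[i, 2, 1] * S[i, 1] + Ic[i, 2, 2] * S[i, 2]
            M[i, i] = S[i, 0] * f0 + S[i, 1] * f1 + S[i, 2] * f2
            j = i
            while parent[j] >= 0:
                j = parent[j]
                M[i, j] = S[j, 0] * f0 + S[j, 1] * f1 + S[j, 2] * f2
                M[j, i] = M[i, j]

        # ---- bias (RNEA with qddot = 0; gravity as base acceleration) -----
        for i in range(nb):
            p = parent[i]
            if p < 0:
                alp = 0.0; aopx = 0.0; aopy = grav
                wp = 0.0
                opx = 0.0; opy = 0.0
            else:
                alp = alph[p]; aopx = ao[p, 0]; aopy = ao[p, 1]
                wp = omg[p]
                opx = o[p, 0]; opy = o[p, 1]
            rx = o[i, 0] - opx
            ry = o[i, 1] - opy
            alph[i] = alp
            aix = aopx - alp * ry - wp * wp * rx
            aiy = aopy + alp * rx - wp * wp * ry
            if jtype[i] != 2:
                adi = jsign[i] * qd[i]
                aix += -2.0 * wp * adi * axw[i, 1]
                aiy += 2.0 * wp * adi * axw[i, 0]
            ao[i, 0] = aix
            ao[i, 1] = aiy
            rcx = cw[i, 0] - o[i, 0]
            rcy = cw[i, 1] - o[i, 1]
            acx = aix - alph[i] * rcy - omg[i] * omg[i] * rcx
            acy = aiy + alph[i] * rcx - omg[i] * omg[i] * rcy
            fb[i, 0] = mass[i] * acx
            fb[i, 1] = mass[i] * acy
            nb_t[i] = inertia[i] * alph[i] + rcx * fb[i, 1] - rcy * fb[i, 0]
        for i in range(nb - 1, -1, -1):
            p = parent[i]
            if p >= 0:
                fb[p, 0] += fb[i, 0]
                fb[p, 1] += fb[i, 1]
                nb_t[p] += nb_t[i] + (o[i, 0] - o[p, 0]) * fb[i, 1] \
                    - (o[i, 1] - o[p, 1]) * fb[i, 0]

        # ---- solve and integrate (semi-implicit Euler) --------------------
        for i in range(nb):
            if jtype[i] == 2:
                bias = nb_t[i]
            else:
                bias = axw[i, 0] * fb[i, 0] + axw[i, 1] * fb[i, 1]
            rhs[i] = tau[i] - bias
        # pinned coordinates: eliminate their rows/columns (zero motion)
        for li in range(locked.shape[0]):
            i = locked[li]
            for j_ in range(nb):
                M[i, j_] = 0.0
                M[j_, i] = 0.0
            M[i, i] = 1.0
            rhs[i] = 0.0
        add = np.linalg.solve(M, rhs)
        for i in range(nb):
            qdd = jsign[i] * add[i]
            qd[i] = qd[i] + qdd * dt
            q[i] = q[i] + qd[i] * dt

    return rows, t_term, fell, effort, dofint


# ---------------------------------------------------------------------------
# Python-facing wrappers
# ---------------------------------------------------------------------------

def run_rollout(model, q0, qd0, act0, *, controller=None, excitations=None,
                amplitude=0.0, frequency=1.0, dt=1e-3, duration=10.0,
                fall_fraction=0.9, knee_limit_deg=30.0, tilt_limit_deg=15.0,
                translation_limit=0.2, penalty_value=10.0, record=True):
    """Run the kernel; returns (records dict | None, scalars dict).

    ``controller`` is a packed controller tuple from
    ``control.pack_controller``; when None, ``excitations`` (length 18,
    constant over the run) drive the muscles open-loop.
    """
    pm = model.packed()
    nsteps = int(round(duration / dt))
    nrec = nsteps + 1 if record else 1
    nm, nc = NM, len(pm.srad)

    rec = {
        "q": np.zeros((nrec, NB)), "qd": np.zeros((nrec, NB)),
        "act": np.zeros((nrec, nm)), "exc": np.zeros((nrec, nm)),
        "F": np.zeros((nrec, nm)), "cn": np.zeros((nrec, nc)),
        "ct": np.zeros((nrec, nc)), "com": np.zeros((nrec, 2)),
        "comv": np.zeros((nrec, 2)), "fcom": np.zeros((nrec, 2)),
        "cop": np.zeros(nrec), "plat": np.zeros((nrec, 2)),
        "grf": np.zeros((nrec, 2)),
    }

    if controller is not None:
        KL, L0, G, KCP, KCV, dm_steps, dcom_steps, ubase = controller
        use_controller = True
        exc_fixed = np.zeros(nm)
    else:
        use_controller = False
        KL = np.zeros(nm); L0 = np.ones(nm); G = np.zeros((nm, nm))
        KCP = np.zeros(nm); KCV = np.zeros(nm)
        dm_steps = np.zeros(nm, dtype=np.int64); dcom_steps = 0; ubase = 0.0
        exc_fixed = np.zeros(nm) if excitations is None \
            else np.asarray(excitations, dtype=float)

    rows, t_term, fell, effort, dofint = _rollout(
        pm.parent, pm.jtype, pm.jsign, pm.jloc, pm.mass, pm.inertia,
        pm.comloc, pm.sbody, pm.sloc, pm.srad, pm.contact,
        pm.fmax, pm.lopt, pm.marm, pm.vmax_rel, pm.tau_act, pm.tau_deact,
        pm.qref, pm.gravity, pm.locked,
        pm.qmin, pm.qmax, pm.klim, pm.dlim,
        np.asarray(q0, dtype=float), np.asarray(qd0, dtype=float),
        np.asarray(act0, dtype=float),
        KL, L0, G, KCP, KCV, dm_steps, np.int64(dcom_steps), float(ubase),
        use_controller, exc_fixed,
        float(amplitude), float(frequency), 0.0, float(dt), nsteps,
        float(fall_fraction), math.radians(knee_limit_deg),
        math.radians(tilt_limit_deg), float(translation_limit),
        float(penalty_value), record,
        rec["q"], rec["qd"], rec["act"], rec["exc"], rec["F"],
        rec["cn"], rec["ct"], rec["com"], rec["comv"], rec["fcom"],
        rec["cop"], rec["plat"], rec["grf"])

    scalars = {"t_term": t_term, "fell": bool(fell), "effort": effort,
               "dof_integral": dofint, "rows": rows, "dt": dt,
               "duration": duration}
    if not record:
        return None, scalars
    for key in rec:
        rec[key] = rec[key][:rows]
    return rec, scalars


def step_once(model, state, excitations, platform_drive, dt):
    """Advance one step open-loop; used by the public ``forward_step``."""
    from .msk_model import SimState
    amp = getattr(platform_drive, "amplitude", 0.0)
    freq = getattr(platform_drive, "frequency", 1.0)
    # shift the drive so the step starts at the state's own time
    t0 = state.t
    pm = model.packed()
    nm = NM
    rec = {k: np.zeros((2, n)) for k, n in (
        ("q", NB), ("qd", NB), ("act", nm), ("exc", nm), ("F", nm),
        ("cn", len(pm.srad)), ("ct", len(pm.srad)), ("com", 2), ("comv", 2),
        ("fcom", 2), ("plat", 2), ("grf", 2))}
    rec["cop"] = np.zeros(2)
    w = 2.0 * math.pi * freq
    phase_amp = amp
    exc = np.asarray(excitations, dtype=float)

    rows, t_term, fell, effort, dofint = _rollout(
        pm.parent, pm.jtype, pm.jsign, pm.jloc, pm.mass, pm.inertia,
        pm.comloc, pm.sbody, pm.sloc, pm.srad, pm.contact,
        pm.fmax, pm.lopt, pm.marm, pm.vmax_rel, pm.tau_act, pm.tau_deact,
        pm.qref, pm.gravity, pm.locked,
        pm.qmin, pm.qmax, pm.klim, pm.dlim,
        state.q[1:].astype(float), state.qdot[1:].astype(float),
        state.act.astype(float),
        np.zeros(nm), np.ones(nm), np.zeros((nm, nm)), np.zeros(nm),
        np.zeros(nm), np.zeros(nm, dtype=np.int64), np.int64(0), 0.0,
        False, exc,
        float(phase_amp), float(freq), float(t0), float(dt), 1,
        0.0, math.radians(30.0), math.radians(15.0), 0.2, 10.0,
        True,
        rec["q"], rec["qd"], rec["act"], rec["exc"], rec["F"],
        rec["cn"], rec["ct"], rec["com"], rec["comv"], rec["fcom"],
        rec["cop"], rec["plat"], rec["grf"])
    if fell and not np.all(np.isfinite(rec["q"][1])):
        raise FloatingPointError("simulation diverged: non-finite state")

    q = np.empty(10); qd = np.empty(10)
    q[1:] = rec["q"][1]; qd[1:] = rec["qd"][1]
    q[0] = amp * math.sin(w * (t0 + dt))
    qd[0] = amp * w * math.cos(w * (t0 + dt))
    return SimState(t0 + dt, q, qd, rec["act"][1])
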