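"""Compiled time-stepping kernels for the monodomain solver.

The reaction step uses a voltage lookup table (linear interpolation) for all
voltage-only rate functions of the detailed atrial model, an exponential
(Rush-Larsen) update for gate variables and a forward step for
concentrations and the membrane potential.  Diffusion enters as a sparse
(CSR) operator applied explicitly each step.  Everything is serial and
deterministic: identical inputs give bit-identical trajectories.

These kernels are internal; ``solver.run_simulation`` and the cell-level
helpers are the public surface.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import cells

__all__ = ["pack_constants", "run_single_cell", "crn_kernel", "ms_kernel"]


# constant-vector layout for the detailed model (see pack_constants)
_CST_NAMES = (
    "F", "RTF", "Cm", "Vi", "Vup", "Vrel", "Ko", "Nao", "Cao",
    "KmNai", "KmKo", "KmNa3", "KmCa", "ksat", "kup", "Ca_up_max",
    "Cmdn_max", "Trpn_max", "Csqn_max", "KmCmdn", "KmTrpn", "KmCsqn",
    "tau_tr", "e_u", "e_fca",
    "gNa", "gK1", "gto", "gKr", "gKs", "gCaL", "gbCa", "gbNa",
    "INaK_max", "INaCa_max", "IpCa_max", "Iup_max", "krel",
)


def pack_constants(dt: float, model_id: str = "atrial_detailed") -> np.ndarray:
    """Baseline constants + conductances as a flat float64 vector."""
    p = cells.make_cell_params("RA", model_id)
    c, g = p.constants, p.conductances
    if model_id == "phenomenological":
        return np.array([g["tau_in"], g["tau_out"], g["tau_open"],
                         g["tau_close"], g["v_gate"], c["V_rest"], c["V_amp"]])
    vals = {
        "F": c["F"], "RTF": c["R"] * c["T"] / c["F"], "Cm": c["Cm_pF"],
        "Vi": c["Vi"], "Vup": c["Vup"], "Vrel": c["Vrel"],
        "Ko": c["Ko"], "Nao": c["Nao"], "Cao": c["Cao"],
        "KmNai": c["KmNai"], "KmKo": c["KmKo"], "KmNa3": c["KmNa"] ** 3,
        "KmCa": c["KmCa"], "ksat": c["ksat"], "kup": c["kup"],
        "Ca_up_max": c["Ca_up_max"], "Cmdn_max": c["Cmdn_max"],
        "Trpn_max": c["Trpn_max"], "Csqn_max": c["Csqn_max"],
        "KmCmdn": c["KmCmdn"], "KmTrpn": c["KmTrpn"], "KmCsqn": c["KmCsqn"],
        "tau_tr": c["tau_tr"], "e_u": math.exp(-dt / c["tau_u"]),
        "e_fca": math.exp(-dt / c["tau_fca"]),
        "gNa": g["gNa"], "gK1": g["gK1"], "gto": g["gto"], "gKr": g["gKr"],
        "gKs": g["gKs"], "gCaL": g["gCaL"], "gbCa": g["gbCa"],
        "gbNa": g["gbNa"], "INaK_max": g["INaK_max"],
        "INaCa_max": g["INaCa_max"], "IpCa_max": g["IpCa_max"],
        "Iup_max": g["Iup_max"], "krel": g["krel"],
    }
    return np.array([vals[k] for k in _CST_NAMES], dtype=np.float64)


@njit(cache=True)
def crn_kernel(V, S, cls, scales, Lp, Li, Lx, dt, n_steps, t0,
               ev_start, ev_end, ev_amp, ev_ptr, ev_nodes,
               win_start, win_end, act, thr,
               tab, vmin, dvinv, cst,
               probe_idx, probe_every, probe_out,
               snap_every, snap_out, err):
    n = V.shape[0]
    stim = np.zeros(n)
    LV = np.zeros(n)
    nw = win_start.shape[0]
    ne = ev_start.shape[0]
    ntab = tab.shape[0]
    has_L = Lx.shape[0] > 0
    nprobe = probe_idx.shape[0]
    prec = 0
    srec = 0

    F = cst[0]; RTF = cst[1]; Cm = cst[2]; Vi = cst[3]; Vup = cst[4]
    Vrel = cst[5]; Ko = cst[6]; Nao = cst[7]; Cao = cst[8]
    KmNai = cst[9]; KmKo = cst[10]; KmNa3 = cst[11]; KmCa = cst[12]
    ksat = cst[13]; kup = cst[14]; caupmax = cst[15]; cmdnmax = cst[16]
    trpnmax = cst[17]; csqnmax = cst[18]; kmcmdn = cst[19]; kmtrpn = cst[20]
    kmcsqn = cst[21]; tautr = cst[22]; e_u = cst[23]; e_fca = cst[24]
    gNa = cst[25]; gK1 = cst[26]; gto = cst[27]; gKr = cst[28]; gKs = cst[29]
    gCaL = cst[30]; gbCa = cst[31]; gbNa = cst[32]; inakmax = cst[33]
    incxmax = cst[34]; ipcamax = cst[35]; iupmax = cst[36]; krel = cst[37]
    FVi = F * Vi
    Nao3 = Nao ** 3
    ncx_den0 = (KmNa3 + Nao3) * (KmCa + Cao)

    rw = np.empty(30)
    for step in range(n_steps):
        t = t0 + step * dt
        for e in range(ne):
            if ev_start[e] == step:
                for q in range(ev_ptr[e], ev_ptr[e + 1]):
                    stim[ev_nodes[q]] += ev_amp[e]
            if ev_end[e] == step:
                for q in range(ev_ptr[e], ev_ptr[e + 1]):
                    stim[ev_nodes[q]] -= ev_amp[e]
        if has_L:
            for i in range(n):
                acc = 0.0
                for q in range(Lp[i], Lp[i + 1]):
                    acc += Lx[q] * V[Li[q]]
                LV[i] = acc

        for i in range(n):
            v = V[i]
            # table row (linear interpolation in V)
            x = (v - vmin) * dvinv
            if x < 0.0:
                x = 0.0
            elif x > ntab - 2.0:
                x = ntab - 2.0
            i0 = int(x)
            fr = x - i0
            for col in range(30):
                rw[col] = tab[i0, col] * (1.0 - fr) + tab[i0 + 1, col] * fr

            sc = scales[cls[i]]
            m = rw[0] + (S[i, 0] - rw[0]) * rw[1]
            hh = rw[2] + (S[i, 1] - rw[2]) * rw[3]
            jj = rw[4] + (S[i, 2] - rw[4]) * rw[5]
            oa = rw[6] + (S[i, 3] - rw[6]) * rw[7]
            oi = rw[8] + (S[i, 4] - rw[8]) * rw[9]
            ua = rw[10] + (S[i, 5] - rw[10]) * rw[11]
            ui = rw[12] + (S[i, 6] - rw[12]) * rw[13]
            xr = rw[14] + (S[i, 7] - rw[14]) * rw[15]
            xs = rw[16] + (S[i, 8] - rw[16]) * rw[17]
            dd = rw[18] + (S[i, 9] - rw[18]) * rw[19]
            ff = rw[20] + (S[i, 10] - rw[20]) * rw[21]
            ww = rw[22] + (S[i, 14] - rw[22]) * rw[23]
            fca = S[i, 11]
            uu = S[i, 12]
            vv = S[i, 13]
            Nai = S[i, 15]
            Ki = S[i, 16]
            Cai = S[i, 17]
            Caup = S[i, 18]
            Carel = S[i, 19]

            ENa = RTF * math.log(Nao / Nai)
            EK = RTF * math.log(Ko / Ki)
            ECa = 0.5 * RTF * math.log(Cao / Cai)

            INa = gNa * sc[0] * m * m * m * hh * jj * (v - ENa)
            IK1 = gK1 * sc[6] * (v - EK) * rw[24]
            Ito = gto * sc[2] * oa * oa * oa * oi * (v - EK)
            IKur = rw[25] * sc[3] * ua * ua * ua * ui * (v - EK)
            IKr = gKr * sc[4] * xr * (v - EK) * rw[26]
            IKs = gKs * sc[5] * xs * xs * (v - EK)
            ICaL = gCaL * sc[1] * dd * ff * fca * (v - 65.0)
            INaK = inakmax * rw[27] / (1.0 + (KmNai / Nai) ** 1.5) * Ko / (Ko + KmKo)
            expg = rw[28]
            expg1 = rw[29]
            INaCa = incxmax * (expg * Nai ** 3 * Cao - expg1 * Nao3 * Cai) \
                / (ncx_den0 * (1.0 + ksat * expg1))
            IbNa = gbNa * (v - ENa)
            IbCa = gbCa * (v - ECa)
            IpCa = ipcamax * Cai / (0.0005 + Cai)

            Irel = krel * uu * uu * vv * ww * (Carel - Cai)
            Fn = 1e-12 * Vrel * Irel - (5e-13 / F) * (0.5 * ICaL - 0.2 * INaCa) * Cm
            uinf = 1.0 / (1.0 + math.exp(-(Fn - 3.4175e-13) / 1.367e-15))
            vinf = 1.0 - 1.0 / (1.0 + math.exp(-(Fn - 6.835e-14) / 1.367e-15))
            tauv = 1.91 + 2.09 / (1.0 + math.exp(-(Fn - 3.4175e-13) / 1.367e-15))
            uu = uinf + (uu - uinf) * e_u
            vv = vinf + (vv - vinf) * math.exp(-dt / tauv)
            fcainf = 1.0 / (1.0 + Cai / 0.00035)
            fca = fcainf + (fca - fcainf) * e_fca

            Itr = (Caup - Carel) / tautr
            Iup = iupmax / (1.0 + kup / Cai)
            Iupleak = iupmax * Caup / caupmax

            dNai = Cm * (-3.0 * INaK - 3.0 * INaCa - IbNa - INa) / FVi
            dKi = Cm * (2.0 * INaK - IK1 - Ito - IKur - IKr - IKs) / FVi
            B1 = Cm * (2.0 * INaCa - IpCa - ICaL - IbCa) / (2.0 * FVi) \
                + (Vup * (Iupleak - Iup) + Irel * Vrel) / Vi
            B2 = 1.0 + trpnmax * kmtrpn / (Cai + kmtrpn) ** 2 \
                + cmdnmax * kmcmdn / (Cai + kmcmdn) ** 2

            Iion = INa + IK1 + Ito + IKur + IKr + IKs + ICaL + IpCa \
                + INaK + INaCa + IbNa + IbCa
            vn = v + dt * (LV[i] - Iion + stim[i])
            if not math.isfinite(vn):
                err[0] = 1.0
                err[1] = float(i)
                err[2] = t
                return
            if vn >= thr and v < thr:
                tc = t + dt * (thr - v) / (vn - v)
                for wdx in range(nw):
                    if win_start[wdx] <= tc < win_end[wdx] and math.isnan(act[wdx, i]):
                        act[wdx, i] = tc

            S[i, 0] = m; S[i, 1] = hh; S[i, 2] = jj; S[i, 3] = oa
            S[i, 4] = oi; S[i, 5] = ua; S[i, 6] = ui; S[i, 7] = xr
            S[i, 8] = xs; S[i, 9] = dd; S[i, 10] = ff; S[i, 11] = fca
            S[i, 12] = uu; S[i, 13] = vv; S[i, 14] = ww
            S[i, 15] = Nai + dt * dNai
            S[i, 16] = Ki + dt * dKi
            S[i, 17] = Cai + dt * B1 / B2
            S[i, 18] = Caup + dt * (Iup - Iupleak - Itr * Vrel / Vup)
            S[i, 19] = Carel + dt * (Itr - Irel) \
                / (1.0 + csqnmax * kmcsqn / (Carel + kmcsqn) ** 2)
            V[i] = vn

        if probe_every > 0 and (step + 1) % probe_every == 0:
            for k in range(nprobe):
                probe_out[prec, k] = V[probe_idx[k]]
            prec += 1
        if snap_every > 0 and (step + 1) % snap_every == 0:
            for i in range(n):
                snap_out[srec, i] = V[i]
            srec += 1


@njit(cache=True)
def ms_kernel(V, S, Lp, Li, Lx, dt, n_steps, t0,
              ev_start, ev_end, ev_amp, ev_ptr, ev_nodes,
              win_start, win_end, act, thr, cst,
              probe_idx, probe_every, probe_out,
              snap_every, snap_out, err):
    """Two-variable excitable model on the same plumbing as crn_kernel."""
    tau_in = cst[0]; tau_out = cst[1]; tau_open = cst[2]
    tau_close = cst[3]; v_gate = cst[4]; v_rest = cst[5]; v_amp = cst[6]
    n = V.shape[0]
    stim = np.zeros(n)
    LV = np.zeros(n)
    nw = win_start.shape[0]
    ne = ev_start.shape[0]
    has_L = Lx.shape[0] > 0
    nprobe = probe_idx.shape[0]
    prec = 0
    srec = 0
    for step in range(n_steps):
        t = t0 + step * dt
        for e in range(ne):
            if ev_start[e] == step:
                for q in range(ev_ptr[e], ev_ptr[e + 1]):
                    stim[ev_nodes[q]] += ev_amp[e]
            if ev_end[e] == step:
                for q in range(ev_ptr[e], ev_ptr[e + 1]):
                    stim[ev_nodes[q]] -= ev_amp[e]
        if has_L:
            for i in range(n):
                acc = 0.0
                for q in range(Lp[i], Lp[i + 1]):
                    acc += Lx[q] * V[Li[q]]
                LV[i] = acc
        for i in range(n):
            v = V[i]
            u = (v - v_rest) / v_amp
            wg = S[i, 0]
            du = wg * u * u * (1.0 - u) / tau_in - u / tau_out \
                + (stim[i] + LV[i]) / v_amp
            if u < v_gate:
                dw = (1.0 - wg) / tau_open
            else:
                dw = -wg / tau_close
            u = u + dt * du
            wg = wg + dt * dw
            if wg < 0.0:
                wg = 0.0
            elif wg > 1.0:
                wg = 1.0
            vn = v_rest + v_amp * u
            if not math.isfinite(vn):
                err[0] = 1.0
                err[1] = float(i)
                err[2] = t
                return
            if vn >= thr and v < thr:
                tc = t + dt * (thr - v) / (vn - v)
                for wdx in range(nw):
                    if win_start[wdx] <= tc < win_end[wdx] and math.isnan(act[wdx, i]):
                        act[wdx, i] = tc
            S[i, 0] = wg
            V[i] = vn
        if probe_every > 0 and (step + 1) % probe_every == 0:
            for k in range(nprobe):
                probe_out[prec, k] = V[probe_idx[k]]
            prec += 1
        if snap_every > 0 and (step + 1) % snap_every == 0:
            for i in range(n):
                snap_out[srec, i] = V[i]
            srec += 1


# ---------------------------------------------------------------------------
# Event/recording plumbing shared by solver.py and the single-cell helper
# ---------------------------------------------------------------------------


def build_events(stimuli, dt, t0, n_nodes):
    """Convert StimulusSpec objects into the kernel's event arrays."""
    starts, ends, amps, ptr, nodes = [], [], [], [0], []
    for st in stimuli:
        s = int(round((st.onset_ms - t0) / dt))
        d = max(1, int(round(st.duration_ms / dt)))
        starts.append(s)
        ends.append(s + d)
        amps.append(float(st.amplitude))
        site = st.site if st.site is not None else range(n_nodes)
        site = np.asarray(list(site), dtype=np.int64)
        nodes.append(site)
        ptr.append(ptr[-1] + site.size)
    if not starts:
        return (np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0),
                np.zeros(1, np.int64), np.zeros(0, np.int64))
    return (np.array(starts, np.int64), np.array(ends, np.int64),
            np.array(amps, float), np.array(ptr, np.int64),
            np.concatenate(nodes).astype(np.int64))


def run_single_cell(params, state, stimuli, duration, dt, record_every=0.1):
    """Advance one isolated cell; returns (t, V trace, final state vector)."""
    state = np.asarray(state, float)
    n_steps = max(1, int(round(duration / dt)))
    probe_every = max(1, int(round(record_every / dt)))
    nrec = n_steps // probe_every
    probe_out = np.empty((nrec, 1))
    probe_idx = np.zeros(1, np.int64)
    ev = build_events(stimuli, dt, 0.0, 1)
    win_start = np.array([0.0])
    win_end = np.array([duration + 1.0])
    act = np.full((1, 1), np.nan)
    err = np.zeros(3)
    empty_L = (np.zeros(2, np.int64), np.zeros(0, np.int64), np.zeros(0))
    snap_out = np.empty((0, 1))
    if params.model_id == "atrial_detailed":
        V = np.array([state[0]])
        S = state[1:].reshape(1, -1).copy()
        scales = params.scale_row().reshape(1, -1)
        cls = np.zeros(1, np.int64)
        tab, vmin, dvinv = cells.build_tables(dt)
        cst = pack_constants(dt)
        crn_kernel(V, S, cls, scales, *empty_L, dt, n_steps, 0.0, *ev,
                   win_start, win_end, act, -40.0, tab, vmin, dvinv, cst,
                   probe_idx, probe_every, probe_out, 0, snap_out, err)
    else:
        V = np.array([state[0]])
        S = state[1:].reshape(1, -1).copy()
        cst = pack_constants(dt, "phenomenological")
        # variant multipliers for the fallback model apply to tau_close
        cst = cst.copy()
        cst[3] *= params.conductances["tau_close"] / \
            cells._DATA["phenomenological"]["conductances"]["tau_close"]
        ms_kernel(V, S, *empty_L, dt, n_steps, 0.0, *ev,
                  win_start, win_end, act, -40.0, cst,
                  probe_idx, probe_every, probe_out, 0, snap_out, err)
    if err[0] != 0:
        raise RuntimeError(f"non-finite membrane potential at t={err[2]:.3f} ms")
    t = dt * probe_every * np.arange(1, nrec + 1)
    t = np.concatenate([[0.0], t])
    vtrace = np.concatenate([[state[0]], probe_out[:, 0]])
    final = np.concatenate([V, S[0]])
    return t, vtrace, final
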