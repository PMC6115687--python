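"""Single-cell ionic kinetics.

Two models are provided behind one parameter interface:

* ``atrial_detailed`` — a biophysically detailed human atrial myocyte model
  (Courtemanche-family formulation: INa, IK1, Ito, IKur, IKr, IKs, ICaL,
  INaK, INaCa, IpCa, background currents, SR calcium handling; 21 state
  variables).  Regional heterogeneity enters through conductance variants:
  ``RA`` (right-atrial working myocardium, baseline) and ``CT`` (conduction
  bundles / crista terminalis, ICaL x1.68 from the same model lineage).

* ``phenomenological`` — a two-variable excitable model (Mitchell-Schaeffer
  form) with tunable action-potential duration, for cheap geometry tests.

All parameter values live in ``data/cell_params.json``; nothing numerical is
hard-coded here except the model equations themselves.  Gate variables are
advanced by exponential (Rush-Larsen) updates, everything else by a forward
step.  ``step_cell`` is a plain-NumPy reference used as the numerics oracle
for the compiled tissue kernel.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "STATE_NAMES",
    "CellParams",
    "StimulusSpec",
    "make_cell_params",
    "apply_block_scaling",
    "initial_state",
    "step_cell",
    "measure_apd_erp",
    "build_tables",
    "SCALED_CONDUCTANCES",
]

# state vector layout of the detailed model: V first, then gates, then
# concentrations.  Gate entries (indices 1..15) are clamped to [0, 1].
STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "Nai", "Ki", "Cai", "Ca_up", "Ca_rel",
)
_GATE_SLICE = slice(1, 16)

# conductances that may carry per-class multipliers in tissue simulations,
# in the column order expected by the solver kernel
SCALED_CONDUCTANCES = ("gNa", "gCaL", "gto", "gKur", "gKr", "gKs", "gK1")


def _load_data() -> dict:
    with resources.files("atriasim.data").joinpath("cell_params.json").open() as fh:
        return json.load(fh)


_DATA = _load_data()


@dataclass(frozen=True)
class CellParams:
    """Frozen parameter set of one model variant."""

    model_id: str
    variant: str
    conductances: Mapping[str, float]
    constants: Mapping[str, float]
    stable_dt_ms: float
    block_scaled: bool = False
    multipliers: Mapping[str, float] = field(default_factory=dict)

    @property
    def Cm_pF(self) -> float:
        return float(self.constants.get("Cm_pF", 100.0))

    def scale_row(self) -> np.ndarray:
        """Multipliers of the kernel-scaled conductances relative to the
        model baseline (column order ``SCALED_CONDUCTANCES``)."""
        base = _DATA[self.model_id]["conductances"]
        row = np.ones(len(SCALED_CONDUCTANCES))
        for i, name in enumerate(SCALED_CONDUCTANCES):
            if name in base and name in self.conductances:
                row[i] = self.conductances[name] / base[name]
        return row


def make_cell_params(variant: str = "RA", model_id: str = "atrial_detailed") -> CellParams:
    """Published parameter set for the chosen variant of the chosen model."""
    if model_id not in _DATA or model_id.startswith("_"):
        raise ValueError(f"unknown model_id {model_id!r}; "
                         f"choose from {[k for k in _DATA if not k.startswith('_')]}")
    entry = _DATA[model_id]
    if variant not in entry["variants"]:
        raise ValueError(f"unknown variant {variant!r} for model {model_id!r}; "
                         f"choose from {sorted(entry['variants'])}")
    cond = dict(entry["conductances"])
    mult = dict(entry["variants"][variant])
    for name, factor in mult.items():
        if name not in cond:
            raise ValueError(f"variant multiplier for unknown conductance {name!r}")
        cond[name] = cond[name] * factor
    return CellParams(model_id=model_id, variant=variant, conductances=cond,
                      constants=dict(entry["constants"]),
                      stable_dt_ms=float(entry["stable_dt_ms"]),
                      multipliers=mult)


def apply_block_scaling(p: CellParams) -> CellParams:
    """Block-zone variant: calcium and sodium conductance reduced to 50%.

    Scales gNa and gCaL (detailed model) by exactly 0.5, leaves everything
    else unchanged, and tags the result so a second application is refused.
    """
    if p.block_scaled:
        raise ValueError("block scaling already applied; re-application forbidden")
    if p.model_id != "atrial_detailed":
        raise ValueError("block scaling is defined for the detailed atrial model")
    cond = dict(p.conductances)
    cond["gNa"] = cond["gNa"] * 0.5
    cond["gCaL"] = cond["gCaL"] * 0.5
    return replace(p, conductances=cond, block_scaled=True)


@dataclass(frozen=True)
class StimulusSpec:
    """External stimulus: amplitude in pA/pF (added directly to dV/dt),
    duration and onset in ms, delivered at ``site`` (a node index set)."""

    amplitude: float
    duration_ms: float
    onset_ms: float = 0.0
    site: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("stimulus amplitude must be positive")
        if not self.duration_ms > 0:
            raise ValueError("stimulus duration must be positive")


def initial_state(params: CellParams) -> np.ndarray:
    init = _DATA[params.model_id]["initial_state"]
    if params.model_id == "atrial_detailed":
        return np.array([init[name] for name in STATE_NAMES], dtype=float)
    return np.array([init["V"], init["w_gate"]], dtype=float)


# ---------------------------------------------------------------------------
# Voltage-dependent rate functions of the detailed model
# ---------------------------------------------------------------------------

_KQ10 = 3.0


def _safe_ratio(num, den, limit):
    """num/den with a finite limit where den -> 0 (removable singularities)."""
    den = np.asarray(den, float)
    small = np.abs(den) < 1e-10
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def gate_inf_exp(V: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Steady states and Rush-Larsen factors exp(-dt/tau) of the 12
    voltage-dependent gates, order (m, h, j, oa, oi, ua, ui, xr, xs, d, f, w).
    """
    V = np.atleast_1d(np.asarray(V, float))
    n = V.shape[0]
    inf = np.empty((n, 12))
    tau = np.empty((n, 12))

    am = _safe_ratio(0.32 * (V + 47.13), 1.0 - np.exp(-0.1 * (V + 47.13)), 3.2)
    bm = 0.08 * np.exp(-V / 11.0)
    inf[:, 0] = am / (am + bm)
    tau[:, 0] = 1.0 / (am + bm)

    low = V < -40.0
    ah = np.where(low, 0.135 * np.exp(-(V + 80.0) / 6.8), 0.0)
    bh = np.where(low, 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
                  1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))))
    inf[:, 1] = ah / (ah + bh)
    tau[:, 1] = 1.0 / (ah + bh)

    aj = np.where(
        low,
        (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
        * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0,
    )
    bj = np.where(
        low,
        0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )
    inf[:, 2] = aj / (aj + bj)
    tau[:, 2] = 1.0 / (aj + bj)

    aoa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    boa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    inf[:, 3] = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    tau[:, 3] = 1.0 / ((aoa + boa) * _KQ10)

    aoi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    boi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    inf[:, 4] = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
    tau[:, 4] = 1.0 / ((aoi + boi) * _KQ10)

    inf[:, 5] = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    tau[:, 5] = 1.0 / ((aoa + boa) * _KQ10)  # ua shares the oa rate shape

    aui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    bui = np.exp((V - 158.0) / 16.0)
    inf[:, 6] = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
    tau[:, 6] = 1.0 / ((aui + bui) * _KQ10)

    axr = _safe_ratio(0.0003 * (V + 14.1), 1.0 - np.exp(-(V + 14.1) / 5.0), 0.0015)
    bxr = _safe_ratio(7.3898e-5 * (V - 3.3328),
                      np.exp((V - 3.3328) / 5.1237) - 1.0, 7.3898e-5 * 5.1237)
    inf[:, 7] = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
    tau[:, 7] = 1.0 / (axr + bxr)

    axs = _safe_ratio(4e-5 * (V - 19.9), 1.0 - np.exp(-(V - 19.9) / 17.0), 4e-5 * 17.0)
    bxs = _safe_ratio(3.5e-5 * (V - 19.9), np.exp((V - 19.9) / 9.0) - 1.0, 3.5e-5 * 9.0)
    inf[:, 8] = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
    tau[:, 8] = 0.5 / (axs + bxs)

    inf[:, 9] = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
    e624 = np.exp(-(V + 10.0) / 6.24)
    tau[:, 9] = _safe_ratio(1.0 - e624, 0.035 * (V + 10.0) * (1.0 + e624),
                            1.0 / (0.035 * 6.24 * 2.0))

    inf[:, 10] = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    tau[:, 10] = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)

    inf[:, 11] = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
    e79 = np.exp(-(V - 7.9) / 5.0)
    tau[:, 11] = _safe_ratio(6.0 * (1.0 - e79), (1.0 + 0.3 * e79) * (V - 7.9),
                             6.0 / (5.0 * 1.3))

    return inf, np.exp(-dt / tau)


def aux_functions(V: np.ndarray) -> np.ndarray:
    """Tabulated voltage-only factors: IK1 rectification, IKur conductance,
    IKr rectification, Na/K-pump voltage factor, and the two NCX
    exponentials.  Order matches the kernel's aux columns."""
    V = np.atleast_1d(np.asarray(V, float))
    c = _DATA["atrial_detailed"]["constants"]
    FRT = c["F"] / (c["R"] * c["T"])
    sigma = (np.exp(c["Nao"] / 67.3) - 1.0) / 7.0
    out = np.empty((V.shape[0], 6))
    out[:, 0] = 1.0 / (1.0 + np.exp(0.07 * (V + 80.0)))
    out[:, 1] = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    out[:, 2] = 1.0 / (1.0 + np.exp((V + 15.0) / 22.4))
    out[:, 3] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * FRT * V)
                       + 0.0365 * sigma * np.exp(-FRT * V))
    out[:, 4] = np.exp(c["gamma"] * FRT * V)
    out[:, 5] = np.exp((c["gamma"] - 1.0) * FRT * V)
    return out


def build_tables(dt: float, vmin: float = -100.0, vmax: float = 60.0,
                 dv: float = 0.02) -> tuple[np.ndarray, float, float]:
    """Voltage lookup table for the tissue kernel at a fixed time step.

    Columns 0..23 interleave (inf, exp(-dt/tau)) for the 12 voltage gates;
    columns 24..29 are the auxiliary voltage factors.  Returns
    (table, vmin, 1/dv); the kernel interpolates linearly in V.
    """
    V = np.arange(vmin, vmax + dv / 2, dv)
    inf, edt = gate_inf_exp(V, dt)
    aux = aux_functions(V)
    tab = np.empty((V.shape[0], 30))
    tab[:, 0:24:2] = inf
    tab[:, 1:24:2] = edt
    tab[:, 24:30] = aux
    return tab, vmin, 1.0 / dv


# ---------------------------------------------------------------------------
# Reference single-cell step (plain NumPy, no tables)
# ---------------------------------------------------------------------------


def _detailed_step(state: np.ndarray, p: CellParams, I_ext: float, dt: float) -> np.ndarray:
    c = p.constants
    g = p.conductances
    V = state[0]
    (m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, v, w,
     Nai, Ki, Cai, Caup, Carel) = state[1:]

    inf, edt = gate_inf_exp(np.array([V]), dt)
    inf, edt = inf[0], edt[0]
    aux = aux_functions(np.array([V]))[0]
    k1r, gkur, krr, fnak, expg, expg1 = aux

    gates = np.array([m, h, j, oa, oi, ua, ui, xr, xs, d, f, w])
    gates = inf + (gates - inf) * edt
    gates = np.clip(gates, 0.0, 1.0)
    m, h, j, oa, oi, ua, ui, xr, xs, d, f, w = gates

    RTF = c["R"] * c["T"] / c["F"]
    ENa = RTF * np.log(c["Nao"] / Nai)
    EK = RTF * np.log(c["Ko"] / Ki)
    ECa = 0.5 * RTF * np.log(c["Cao"] / Cai)

    INa = g["gNa"] * m ** 3 * h * j * (V - ENa)
    IK1 = g["gK1"] * (V - EK) * k1r
    Ito = g["gto"] * oa ** 3 * oi * (V - EK)
    IKur = gkur * ua ** 3 * ui * (V - EK)
    IKr = g["gKr"] * xr * (V - EK) * krr
    IKs = g["gKs"] * xs ** 2 * (V - EK)
    ICaL = g["gCaL"] * d * f * fca * (V - 65.0)
    INaK = g["INaK_max"] * fnak / (1.0 + (c["KmNai"] / Nai) ** 1.5) \
        * c["Ko"] / (c["Ko"] + c["KmKo"])
    INaCa = g["INaCa_max"] * (expg * Nai ** 3 * c["Cao"] - expg1 * c["Nao"] ** 3 * Cai) \
        / ((c["KmNa"] ** 3 + c["Nao"] ** 3) * (c["KmCa"] + c["Cao"])
           * (1.0 + c["ksat"] * expg1))
    IbNa = g["gbNa"] * (V - ENa)
    IbCa = g["gbCa"] * (V - ECa)
    IpCa = g["IpCa_max"] * Cai / (0.0005 + Cai)

    Irel = g["krel"] * u ** 2 * v * w * (Carel - Cai)
    Cm = c["Cm_pF"]
    Fn = 1e-12 * c["Vrel"] * Irel - (5e-13 / c["F"]) * (0.5 * ICaL - 0.2 * INaCa) * Cm
    uinf = 1.0 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 1.367e-15))
    vinf = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 1.367e-15))
    tauv = 1.91 + 2.09 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 1.367e-15))
    u = uinf + (u - uinf) * np.exp(-dt / c["tau_u"])
    v = vinf + (v - vinf) * np.exp(-dt / tauv)
    fcainf = 1.0 / (1.0 + Cai / 0.00035)
    fca = fcainf + (fca - fcainf) * np.exp(-dt / c["tau_fca"])
    u, v, fca = np.clip([u, v, fca], 0.0, 1.0)

    Itr = (Caup - Carel) / c["tau_tr"]
    Iup = g["Iup_max"] / (1.0 + c["kup"] / Cai)
    Iupleak = g["Iup_max"] * Caup / c["Ca_up_max"]

    FVi = c["F"] * c["Vi"]
    dNai = Cm * (-3.0 * INaK - 3.0 * INaCa - IbNa - INa) / FVi
    dKi = Cm * (2.0 * INaK - IK1 - Ito - IKur - IKr - IKs) / FVi
    B1 = Cm * (2.0 * INaCa - IpCa - ICaL - IbCa) / (2.0 * FVi) \
        + (c["Vup"] * (Iupleak - Iup) + Irel * c["Vrel"]) / c["Vi"]
    B2 = 1.0 + c["Trpn_max"] * c["KmTrpn"] / (Cai + c["KmTrpn"]) ** 2 \
        + c["Cmdn_max"] * c["KmCmdn"] / (Cai + c["KmCmdn"]) ** 2
    dCai = B1 / B2
    dCaup = Iup - Iupleak - Itr * c["Vrel"] / c["Vup"]
    dCarel = (Itr - Irel) / (1.0 + c["Csqn_max"] * c["KmCsqn"] / (Carel + c["KmCsqn"]) ** 2)

    Iion = (INa + IK1 + Ito + IKur + IKr + IKs + ICaL + IpCa + INaK + INaCa
            + IbNa + IbCa)
    Vn = V + dt * (-Iion + I_ext)

    out = np.array([Vn, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, v, w,
                    Nai + dt * dNai, Ki + dt * dKi, Cai + dt * dCai,
                    Caup + dt * dCaup, Carel + dt * dCarel])
    return out


def _phenom_step(state: np.ndarray, p: CellParams, I_ext: float, dt: float) -> np.ndarray:
    c, g = p.constants, p.conductances
    u = (state[0] - c["V_rest"]) / c["V_amp"]
    wg = state[1]
    du = wg * u * u * (1.0 - u) / g["tau_in"] - u / g["tau_out"] + I_ext / c["V_amp"]
    dw = (1.0 - wg) / g["tau_open"] if u < g["v_gate"] else -wg / g["tau_close"]
    u = u + dt * du
    wg = min(max(wg + dt * dw, 0.0), 1.0)
    return np.array([c["V_rest"] + c["V_amp"] * u, wg])


def step_cell(state: np.ndarray, params: CellParams, I_ext: float, dt: float) -> np.ndarray:
    """Advance one cell by ``dt`` ms.  ``I_ext`` is in pA/pF and is added
    directly to dV/dt (capacitance-normalized stimulus convention)."""
    if dt > params.stable_dt_ms + 1e-12:
        raise ValueError(f"dt={dt} exceeds the model's stable dt "
                         f"({params.stable_dt_ms} ms)")
    state = np.asarray(state, float)
    if params.model_id == "atrial_detailed":
        out = _detailed_step(state, params, I_ext, dt)
    else:
        out = _phenom_step(state, params, I_ext, dt)
    if not np.all(np.isfinite(out)):
        names = STATE_NAMES if params.model_id == "atrial_detailed" else ("V", "w_gate")
        bad = [names[i] for i in np.flatnonzero(~np.isfinite(out))]
        raise RuntimeError(f"non-finite state variables after step: {bad}")
    return out


# ---------------------------------------------------------------------------
# APD / ERP measurement (single cell, via the compiled kernel)
# ---------------------------------------------------------------------------


def _single_cell_run(params, state, stimuli, duration, dt, record_every=0.1):
    """Run one isolated cell with the tissue kernel (zero diffusion)."""
    from . import _kernel
    return _kernel.run_single_cell(params, state, stimuli, duration, dt, record_every)


def _apd90(t: np.ndarray, vtrace: np.ndarray, onset: float) -> float:
    seg = (t >= onset) & (t <= onset + 600.0)
    ts, vs = t[seg], vtrace[seg]
    vrest = vs[0]
    ipk = int(np.argmax(vs))
    vpeak = vs[ipk]
    v90 = vpeak - 0.9 * (vpeak - vrest)
    below = np.flatnonzero(vs[ipk:] <= v90)
    if below.size == 0:
        return float("nan")
    iup = np.flatnonzero(vs >= -40.0)
    t_up = ts[iup[0]] if iup.size else ts[0]
    return float(ts[ipk + below[0]] - t_up)


def measure_apd_erp(params: CellParams, pacing_cl: float, n_beats: int,
                    dt: float | None = None,
                    stim_amplitude: float = 20.0, stim_duration: float = 2.0,
                    ) -> tuple[float, float]:
    """APD90 of the last paced beat and ERP by S2 bisection to 1 ms.

    A premature (S2) beat *captures* when its action-potential amplitude
    exceeds 80% of the last S1 amplitude.  Returns (APD90 ms, ERP ms).
    """
    if n_beats <= 0:
        raise ValueError("n_beats must be positive (the cell must be paced)")
    dt = dt or params.stable_dt_ms
    state0 = initial_state(params)
    stimuli = [StimulusSpec(stim_amplitude, stim_duration, onset_ms=k * pacing_cl)
               for k in range(n_beats)]
    last_onset = (n_beats - 1) * pacing_cl
    t, vtrace, state_end = _single_cell_run(
        params, state0, stimuli, duration=last_onset + 5.0, dt=dt)
    # continue the last beat without a following stimulus to measure APD90
    t2, v2, state_after = _single_cell_run(
        params, state_end, [], duration=600.0, dt=dt)
    full_t = np.concatenate([t, last_onset + 5.0 + t2])
    full_v = np.concatenate([vtrace, v2])
    apd = _apd90(full_t, full_v, last_onset)

    vrest = float(vtrace[0])
    i0 = np.searchsorted(full_t, last_onset)
    s1_amp = float(full_v[i0:].max() - vrest)

    def captures(s2: float) -> bool:
        # state_end sits 5 ms after the last S1 onset, so the S2 stimulus
        # lands at coupling interval s2 when delivered at s2 - 5
        onset = s2 - 5.0
        tt, vv, _ = _single_cell_run(params, state_end,
                                     [StimulusSpec(stim_amplitude, stim_duration,
                                                   onset_ms=onset)],
                                     duration=onset + 300.0, dt=dt)
        i_on = int(np.searchsorted(tt, onset))
        take_off = float(vv[i_on])
        amp2 = float(vv[i_on:].max() - take_off)
        return amp2 > 0.8 * s1_amp

    lo, hi = 50.0, max(2.0 * pacing_cl, 600.0)
    if not captures(hi):
        return apd, float("nan")
    while hi - lo > 1.0:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return apd, float(hi)
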