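"""Anisotropic monodomain solver and conduction-velocity calibration.

Advances dV/dt = div(D grad V) - I_ion + I_stim on the active-node graph of
a :class:`~atriasim.tissue.TissueModel` by operator splitting: an explicit
sparse diffusion step and a tabulated Rush-Larsen reaction step per time
step.  Zero-flux boundaries are built into the diffusion operator; inert
nodes carry no state.  The solver is serial and fully deterministic.

Conduction velocity is measured between probes at 25% and 75% of a
preparation's extent (away from stimulus and boundary artefacts), and
``calibrate_diffusion`` bisects the longitudinal diffusion coefficient of a
fiber-aligned strand until the target velocity (68.2 cm/s for RA tissue by
default) is met.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

from . import _kernel, cells
from .cells import StimulusSpec
from .tissue import TissueModel, strand_model

__all__ = [
    "SolverConfig",
    "SimulationResult",
    "CalibrationResult",
    "run_simulation",
    "measure_cv",
    "calibrate_diffusion",
]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration of the operator-splitting integrator.

    ``dt_ms`` defaults to the detailed model's stable Rush-Larsen step
    (0.02 ms; halving it changes single-cell peak potentials by well under
    0.5 mV and measured CV by under 2%).  Explicit diffusion additionally
    requires dt <= cfl_safety * h^2 / (2 * max trace D), which
    ``run_simulation`` enforces.
    """

    dt_ms: float = 0.02
    duration_ms: float = 100.0
    output_interval_ms: float = 1.0
    snapshot_interval_ms: float = 0.0   # 0 disables full-field snapshots
    cfl_safety: float = 0.9
    activation_threshold_mv: float = -40.0

    def __post_init__(self) -> None:
        if not self.dt_ms > 0 or not self.duration_ms > 0:
            raise ValueError("dt_ms and duration_ms must be positive")
        if self.output_interval_ms < self.dt_ms:
            raise ValueError("output_interval_ms must be >= dt_ms")


@dataclass
class SimulationResult:
    """Sampled voltages, per-beat activation times and the final state."""

    t0: float
    times: np.ndarray            # probe sampling times (ms)
    probe_idx: np.ndarray
    probe_v: np.ndarray          # (n_times, n_probes)
    windows: np.ndarray          # (n_beats, 2) ms
    activation: np.ndarray       # (n_beats, n_nodes); NaN = not activated
    snapshot_times: np.ndarray
    snapshots: np.ndarray        # (n_snap, n_nodes)
    final_state: tuple[np.ndarray, np.ndarray]
    config: SolverConfig
    stimuli: list[StimulusSpec]
    n_nodes: int
    meta: dict[str, Any] = field(default_factory=dict)


def _stable_dt(model: TissueModel, config: SolverConfig) -> float:
    tr = model.max_trace()
    if tr <= 0:
        return config.dt_ms
    return config.cfl_safety * model.spacing_mm ** 2 / (2.0 * tr)


def run_simulation(
    model: TissueModel,
    stimuli: Sequence[StimulusSpec],
    config: SolverConfig,
    initial_state: tuple[np.ndarray, np.ndarray] | None = None,
    t0: float = 0.0,
    windows: np.ndarray | None = None,
    probes: Sequence[int] | None = None,
) -> SimulationResult:
    """Advance the coupled reaction-diffusion system.

    ``initial_state`` accepts the ``final_state`` of a previous run for
    checkpoint restarts; ``windows`` are (start, end) activation-detection
    intervals in absolute ms (default: one window per stimulus onset,
    extending to the next onset or the end of the run).
    """
    n = model.n_nodes
    stimuli = list(stimuli)
    for st in stimuli:
        if st.site is not None and len(st.site) and \
                (np.max(st.site) >= n or np.min(st.site) < 0):
            raise ValueError("stimulus site outside the active-node range")
        if st.onset_ms < t0 - 1e-9 or st.onset_ms > t0 + config.duration_ms:
            raise ValueError(f"stimulus onset {st.onset_ms} outside the run window")

    dt = config.dt_ms
    dt_max = _stable_dt(model, config)
    if dt > dt_max + 1e-12:
        raise ValueError(
            f"explicit diffusion is unstable at dt={dt} ms for this model; "
            f"maximal admissible dt = {dt_max:.5f} ms "
            f"(h={model.spacing_mm} mm, max trace D={model.max_trace():.4f})")

    if model.model_id == "atrial_detailed":
        params = cells.make_cell_params("RA")
        full0 = cells.initial_state(params)
    else:
        params = cells.make_cell_params("RA", "phenomenological")
        full0 = cells.initial_state(params)
    if initial_state is None:
        V = np.full(n, full0[0])
        S = np.tile(full0[1:], (n, 1))
    else:
        V = initial_state[0].copy()
        S = initial_state[1].copy()
        if V.shape[0] != n:
            raise ValueError("initial_state does not match the node count")

    if windows is None:
        onsets = sorted(st.onset_ms for st in stimuli)
        if not onsets:
            windows = np.array([[t0, t0 + config.duration_ms]])
        else:
            edges = onsets + [t0 + config.duration_ms]
            windows = np.array([[edges[k], edges[k + 1]] for k in range(len(onsets))])
    windows = np.asarray(windows, float)

    n_steps = max(1, int(round(config.duration_ms / dt)))
    probe_idx = np.asarray(list(probes) if probes is not None else [0], np.int64)
    probe_every = max(1, int(round(config.output_interval_ms / dt)))
    n_rec = n_steps // probe_every
    probe_out = np.empty((n_rec, probe_idx.size))
    snap_every = 0
    snap_out = np.empty((0, n))
    if config.snapshot_interval_ms > 0:
        snap_every = max(1, int(round(config.snapshot_interval_ms / dt)))
        snap_out = np.empty((n_steps // snap_every, n))

    lap = model.laplacian()
    ev = _kernel.build_events(stimuli, dt, t0, n)
    act = np.full((windows.shape[0], n), np.nan)
    err = np.zeros(3)
    if model.model_id == "atrial_detailed":
        tab, vmin, dvinv = cells.build_tables(dt)
        cst = _kernel.pack_constants(dt)
        _kernel.crn_kernel(V, S, model.node_class.astype(np.int64),
                           model.scale_rows(), lap.indptr.astype(np.int64),
                           lap.indices.astype(np.int64), lap.data,
                           dt, n_steps, t0, *ev,
                           windows[:, 0].copy(), windows[:, 1].copy(), act,
                           config.activation_threshold_mv, tab, vmin, dvinv, cst,
                           probe_idx, probe_every, probe_out,
                           snap_every, snap_out, err)
    else:
        cst = _kernel.pack_constants(dt, "phenomenological")
        _kernel.ms_kernel(V, S, lap.indptr.astype(np.int64),
                          lap.indices.astype(np.int64), lap.data,
                          dt, n_steps, t0, *ev,
                          windows[:, 0].copy(), windows[:, 1].copy(), act,
                          config.activation_threshold_mv, cst,
                          probe_idx, probe_every, probe_out,
                          snap_every, snap_out, err)
    if err[0] != 0:
        i = int(err[1])
        raise RuntimeError(
            f"non-finite membrane potential at node {i} "
            f"(voxel {tuple(model.coords[i])}) at t={err[2]:.3f} ms")

    times = t0 + dt * probe_every * np.arange(1, n_rec + 1)
    snap_times = t0 + dt * snap_every * np.arange(1, snap_out.shape[0] + 1) \
        if snap_every else np.zeros(0)
    return SimulationResult(
        t0=t0, times=times, probe_idx=probe_idx, probe_v=probe_out,
        windows=windows, activation=act, snapshot_times=snap_times,
        snapshots=snap_out, final_state=(V, S), config=config,
        stimuli=stimuli, n_nodes=n)


# ---------------------------------------------------------------------------
# Conduction-velocity measurement and calibration
# ---------------------------------------------------------------------------


def measure_cv(
    result: SimulationResult,
    model: TissueModel,
    frac: tuple[float, float] = (0.25, 0.75),
    axis: int = 0,
    window: int = 0,
) -> float:
    """Planar-wave conduction velocity in cm/s between two fractional
    positions along ``axis`` (default 25% and 75%, away from the ends).

    Returns NaN if the wave did not reach both probes.
    """
    act = result.activation[window]
    pos = model.coords[:, axis].astype(float)
    lo, hi = pos.min(), pos.max()
    others = [a for a in range(3) if a != axis]
    centre = [np.median(model.coords[:, a]) for a in others]
    picks = []
    for fr in frac:
        target = lo + fr * (hi - lo)
        cost = np.abs(pos - target)
        for a, c in zip(others, centre):
            cost = cost + np.abs(model.coords[:, a] - c)
        picks.append(int(np.argmin(cost)))
    i1, i2 = picks
    t1, t2 = act[i1], act[i2]
    if not (np.isfinite(t1) and np.isfinite(t2)) or t2 == t1:
        return float("nan")
    dist_mm = np.linalg.norm(
        (model.coords[i2] - model.coords[i1]).astype(float)) * model.spacing_mm
    return float(abs(dist_mm / (t2 - t1)) * 100.0)  # mm/ms -> cm/s


@dataclass(frozen=True)
class CalibrationResult:
    d_l: float
    cv_cm_s: float
    target_cv_cm_s: float
    iterations: int
    h_mm: float
    dt_ms: float
    ratio: float
    cell_class: str

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("d_l", "cv_cm_s", "target_cv_cm_s", "iterations",
                 "h_mm", "dt_ms", "ratio", "cell_class")}


def _strand_cv(d_l: float, cell_class: str, h: float, ratio: float,
               config: SolverConfig, length_mm: float,
               stim_amplitude: float, stim_duration: float) -> float:
    model = strand_model(length_mm=length_mm, h=h, d_l=d_l, ratio=ratio,
                         cell_class=cell_class)
    dt_max = _stable_dt(model, config)
    cfg = config if config.dt_ms <= dt_max else replace(config, dt_ms=dt_max)
    # stimulate a ~1.2 mm end segment: a 1-voxel point source cannot charge
    # the diffusive load of a well-coupled strand
    n_site = max(3, int(round(1.2 / h)))
    stim = StimulusSpec(stim_amplitude, stim_duration, onset_ms=1.0,
                        site=tuple(range(min(n_site, model.n_nodes))))
    res = run_simulation(model, [stim], cfg)
    return measure_cv(res, model)


def calibrate_diffusion(
    target_cv: float = 68.2,
    cell_class: str = "RA",
    h: float = 0.15,
    ratio: float = 8.0,
    config: SolverConfig | None = None,
    tol_cv: float = 0.1,
    strand_length_mm: float = 20.0,
    bracket: tuple[float, float] = (1e-4, 1.0),
    stim_amplitude: float = 20.0,
    stim_duration: float = 2.0,
    max_iter: int = 60,
) -> CalibrationResult:
    """Bisect the longitudinal diffusion coefficient d_l (mm^2/ms) of a
    fiber-aligned strand until the measured CV matches ``target_cv`` cm/s
    to within ``tol_cv``.

    CV grows monotonically with d_l (approximately as sqrt(d_l)); failed
    conduction counts as 'too slow'.  Raises if the bracket cannot span the
    target, reporting the achievable CV range.
    """
    if not target_cv > 0:
        raise ValueError("target_cv must be positive")
    config = config or SolverConfig(
        duration_ms=max(60.0, strand_length_mm / 0.2 + 20.0),
        output_interval_ms=1.0)

    def cv_of(d):
        v = _strand_cv(d, cell_class, h, ratio, config, strand_length_mm,
                       stim_amplitude, stim_duration)
        return v if math.isfinite(v) else 0.0

    lo, hi = bracket
    cv_lo, cv_hi = cv_of(lo), cv_of(hi)
    iters = 2
    # at very large d the strand is nearly isopotential and initiation fails;
    # shrink the upper bracket until a wave propagates
    while cv_hi <= 0.0 and hi > 4.0 * lo and iters < max_iter:
        hi *= 0.5
        cv_hi = cv_of(hi)
        iters += 1
    if not (cv_lo < target_cv < cv_hi):
        raise ValueError(
            f"target CV {target_cv} cm/s outside the achievable range "
            f"[{cv_lo:.1f}, {cv_hi:.1f}] cm/s for d_l in {bracket}")
    d_mid, cv_mid = lo, cv_lo
    for _ in range(max_iter):
        d_mid = math.sqrt(lo * hi)  # geometric mean: CV ~ sqrt(d)
        cv_mid = cv_of(d_mid)
        iters += 1
        if abs(cv_mid - target_cv) <= tol_cv:
            break
        if cv_mid < target_cv:
            lo = d_mid
        else:
            hi = d_mid
    else:
        raise RuntimeError(
            f"calibration did not converge: best CV {cv_mid:.2f} cm/s "
            f"(target {target_cv} +/- {tol_cv})")
    return CalibrationResult(d_l=float(d_mid), cv_cm_s=float(cv_mid),
                             target_cv_cm_s=float(target_cv), iterations=iters,
                             h_mm=h, dt_ms=config.dt_ms, ratio=ratio,
                             cell_class=cell_class)
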