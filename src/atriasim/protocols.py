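"""Pacing protocols and activation analysis.

Implements the S1-S2 study design: a conditioning train of S1 stimuli at the
sinus node (20 pA/pF, 2 ms), one premature S2 with fast-pacing settings
(40 pA/pF, 4 ms) at coupling intervals swept across 250-400 ms, and the
readouts built on activation maps: isochrone bands, earliest pathway arrival
at the compact-node region (fast-minus-slow difference), per-route
propagation direction (anterograde / retrograde), whole-tissue capture and
the stimulus:activation ratio under sustained sub-boundary pacing.

A beat *captures* when at least ``capture_fraction`` (default 90%) of the
active nodes activate inside the beat window; "atrial activation" is not
otherwise quantified, so the fraction is configuration-exposed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .cells import StimulusSpec
from .phantoms import LabelDictionary, default_label_dictionary
from .solver import SimulationResult, SolverConfig, run_simulation
from .tissue import TissueModel

__all__ = [
    "PacingProtocol",
    "ActivationMap",
    "PathwayReport",
    "S1S2Result",
    "compute_activation_map",
    "isochrones",
    "pathway_arrival",
    "propagation_direction",
    "detect_block",
    "find_min_capturing_s2",
    "run_sinus_beat",
    "run_s1_train",
    "run_s1s2_sweep",
    "run_repeated_pacing",
]


@dataclass(frozen=True)
class PacingProtocol:
    """S1-S2 pacing at the sinus node."""

    s1_count: int = 8
    s1_cycle_ms: float = 400.0
    s2_list: tuple[float, ...] = (250.0, 275.0, 300.0, 350.0, 400.0)
    s1_amplitude: float = 20.0      # pA/pF
    s1_duration_ms: float = 2.0
    s2_amplitude: float = 40.0      # fast-pacing stimulus
    s2_duration_ms: float = 4.0
    site_label: str = "sinus_node"
    capture_fraction: float = 0.9
    observation_ms: float = 300.0   # window after the S2 onset

    def __post_init__(self) -> None:
        if self.s1_count < 1:
            raise ValueError("s1_count must be >= 1")
        s2 = tuple(self.s2_list)
        if list(s2) != sorted(s2):
            raise ValueError("s2_list must be sorted ascending")
        if s2 and s2[-1] > self.s1_cycle_ms:
            raise ValueError("S2 intervals must not exceed the S1 cycle length")


@dataclass
class ActivationMap:
    """Per-node activation time of one beat (ms; NaN = not activated)."""

    times: np.ndarray
    window: tuple[float, float]
    threshold_mv: float
    spacing_mm: float
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def nan_fraction(self) -> float:
        return float(np.mean(~np.isfinite(self.times)))

    @property
    def activated_fraction(self) -> float:
        return 1.0 - self.nan_fraction


def compute_activation_map(result: SimulationResult, beat: int,
                           model: TissueModel) -> ActivationMap:
    """Activation time = first upward crossing of the threshold (default
    -40 mV) inside the beat's window, sub-step interpolated."""
    if not 0 <= beat < result.windows.shape[0]:
        raise IndexError(f"beat {beat} outside the recorded windows")
    return ActivationMap(result.activation[beat].copy(),
                         (float(result.windows[beat, 0]),
                          float(result.windows[beat, 1])),
                         result.config.activation_threshold_mv,
                         0.0)


def isochrones(amap: ActivationMap, interval_ms: float) -> tuple[np.ndarray, int]:
    """Equal-activation-time bands: band k holds nodes with time (relative
    to the earliest activation) in [k*interval, (k+1)*interval).  Returns
    (band index per node, -1 for unactivated; number of bands)."""
    if not interval_ms > 0:
        raise ValueError("interval_ms must be positive")
    t = amap.times
    ok = np.isfinite(t)
    bands = np.full(t.shape, -1, dtype=int)
    if not ok.any():
        return bands, 0
    t0, t1 = t[ok].min(), t[ok].max()
    span = t1 - t0
    n_bands = max(1, int(math.ceil(span / interval_ms))) if span > 0 else 1
    k = np.floor((t[ok] - t0) / interval_ms).astype(int)
    bands[ok] = np.minimum(k, n_bands - 1)
    return bands, n_bands


@dataclass
class PathwayReport:
    """Earliest arrival at the compact-node region via each labeled route."""

    arrivals: dict[str, float]            # NaN when the route never arrives
    order: list[str]                      # routes sorted by arrival time
    fast_minus_slow_ms: float             # NaN unless both arrive
    directions: dict[str, str]            # anterograde / retrograde / none
    beat_window: tuple[float, float]


def _route_samples(model: TissueModel, route: Mapping,
                   dictionary: LabelDictionary):
    """Arc-length coordinate and activation index of every route voxel."""
    codes = [dictionary.code(l) for l in route["labels"]]
    idx = np.flatnonzero(np.isin(model.node_label, codes))
    if idx.size == 0:
        return idx, np.zeros(0)
    pts = np.asarray(route["points"], float)
    arclen = np.asarray(route["arclength"], float)
    pos = model.positions_mm()[idx][:, :2]
    _, nearest = cKDTree(pts).query(pos, k=1)
    return idx, arclen[nearest]


def _route_front_arrival(
    amap: ActivationMap,
    model: TissueModel,
    route: Mapping,
    dictionary: LabelDictionary,
    window_mm: float = 0.8,
    min_points: int = 8,
    fit_points: int = 300,
    end_margin_mm: float = 1.2,
    block_gap_ms: float = 15.0,
) -> float:
    """Time the route's own node-ward (anterograde) wavefront reaches the
    route's nodal end.

    Once the compact node fires via the first route, its activation spills
    backward into the other routes' insertions; a plain minimum over
    near-node voxels would report that spill, not the route's conduction.
    Front voxels are identified by their local time ordering along the
    route's arc length (upstream neighbours activated earlier, downstream
    ones not earlier), a robust Theil-Sen line of time versus arc length is
    fitted to them, and the arrival is that line evaluated at the route's
    full length.  If the front met the opposing (node-side) spill mid-route
    — a collision, recognisable because the two fronts meet at nearly the
    same time — the extrapolation still measures when this route's
    activation reached the node's vicinity.  If instead the front *blocked*
    (nothing distal activates, or the distal segment activates only much
    later and backwards), the route never arrived: NaN.
    """
    idx, s = _route_samples(model, route, dictionary)
    t = amap.times[idx] if idx.size else np.zeros(0)
    ok = np.isfinite(t)
    if ok.sum() < min_points:
        return float("nan")
    s, t = s[ok], t[ok]
    order = np.argsort(s, kind="stable")
    s, t = s[order], t[order]
    up_lo = np.searchsorted(s, s - window_mm, side="left")
    up_hi = np.searchsorted(s, s - 0.05, side="right")
    dn_lo = np.searchsorted(s, s + 0.05, side="left")
    dn_hi = np.searchsorted(s, s + window_mm, side="right")
    ant = np.zeros(s.size, bool)
    for i in range(s.size):
        if up_hi[i] <= up_lo[i]:
            continue
        if t[up_lo[i]:up_hi[i]].min() >= t[i]:
            continue
        if dn_hi[i] > dn_lo[i] and t[dn_lo[i]:dn_hi[i]].min() < t[i]:
            continue  # node-side spill: downstream fired first
        ant[i] = True
    aidx = np.flatnonzero(ant)
    if aidx.size < min_points:
        return float("nan")
    # the front segment must be contiguous from the proximal end: isolated
    # distal clusters (edge voxels of a retrograde wave) are not the front
    gaps = np.diff(s[aidx])
    cut = np.flatnonzero(gaps > 1.0)
    if cut.size:
        aidx = aidx[:cut[0] + 1]
    if aidx.size < min_points:
        return float("nan")
    ant = np.zeros(s.size, bool)
    ant[aidx] = True
    sc, tc = s[ant], t[ant]
    if sc.size > fit_points:  # theilslopes is O(n^2) in pairs
        stride = sc.size // fit_points + 1
        sc, tc = sc[::stride], tc[::stride]
    slope = stats.theilslopes(tc, sc)[0]
    if slope <= 0:
        return float("nan")
    intercept = float(np.median(t[ant] - slope * s[ant]))
    length = float(np.asarray(route["arclength"])[-1])
    s_front = float(np.percentile(s[ant], 97))
    # the node region swallows the route's last voxels, so "reached the
    # end" means reaching the last *available* route voxels — provided
    # those extend to the node's vicinity at all
    s_max = float(s.max())
    end_reached = s_front >= length - end_margin_mm or \
        (s_max >= length - 2.0 and s_front >= s_max - 0.6)
    if end_reached:
        return intercept + slope * length
    # the front stopped mid-route: collision with the opposing (node-side)
    # front, or true block?  In a collision the distal segment activated at
    # times consistent with the extrapolated front line; after a block it
    # activates only much later (retrogradely) or not at all.  The probe
    # window starts 0.5 mm beyond the front to skip the die-off tail.
    probe = (s > s_front + 0.5) & (s <= min(s_front + 3.0, float(s.max())))
    if not probe.any():
        return float("nan")  # nothing beyond the front ever activated
    gap = float(np.median(t[probe] - (intercept + slope * s[probe])))
    if gap > block_gap_ms:
        return float("nan")  # block: distal segment fired by a later event
    return intercept + slope * length  # collision with the opposing front


def pathway_arrival(
    amap: ActivationMap,
    model: TissueModel,
    routes: Mapping[str, Mapping],
    dictionary: LabelDictionary | None = None,
    node_label: str = "compact_AV_node",
    fast_route: str = "fast",
    slow_route: str = "slow",
) -> PathwayReport:
    """Earliest arrival of each route's own wavefront at the compact-node
    region.

    ``routes`` is the geometry's route metadata (labels + centerline); the
    arrival difference is fast-route minus slow-route (positive when the
    slow pathway reaches the node first, as in sinus rhythm on the AVSD
    geometry).  A route whose insertion is only reached retrogradely (from
    the node side) reports NaN arrival and direction "retrograde"/"none".
    """
    ldict = dictionary or default_label_dictionary()
    arrivals: dict[str, float] = {}
    directions: dict[str, str] = {}
    for name, route in routes.items():
        idx, _ = _route_samples(model, route, ldict)
        if idx.size == 0:
            raise ValueError(f"route {name!r} has no active voxels")
        arrivals[name] = _route_front_arrival(amap, model, route, ldict)
        directions[name] = propagation_direction(amap, model, route, ldict)
    order = sorted([r for r in arrivals if np.isfinite(arrivals[r])],
                   key=lambda r: arrivals[r])
    f, s = arrivals.get(fast_route, np.nan), arrivals.get(slow_route, np.nan)
    diff = f - s if np.isfinite(f) and np.isfinite(s) else float("nan")
    return PathwayReport(arrivals, order, float(diff), directions,
                         amap.window)


def propagation_direction(
    amap: ActivationMap,
    model: TissueModel,
    route: Mapping,
    dictionary: LabelDictionary | None = None,
    min_activated_fraction: float = 0.3,
    slope_resolution_ms: float = 1.0,
) -> str:
    """Sign of the robust (Theil-Sen) slope of activation time versus arc
    length along the route centerline: positive (times increase toward the
    node) = anterograde, negative = retrograde, below resolution or mostly
    unactivated = none."""
    ldict = dictionary or default_label_dictionary()
    codes = [ldict.code(l) for l in route["labels"]]
    idx = np.flatnonzero(np.isin(model.node_label, codes))
    if idx.size == 0:
        return "none"
    pts = np.asarray(route["points"], float)
    arclen = np.asarray(route["arclength"], float)
    pos = model.positions_mm()[idx][:, :2]
    _, nearest = cKDTree(pts).query(pos, k=1)
    s = arclen[nearest]
    t = amap.times[idx]
    ok = np.isfinite(t)
    if ok.sum() < max(5, min_activated_fraction * idx.size):
        return "none"
    slope, _, _, _ = stats.theilslopes(t[ok], s[ok])
    length = float(arclen[-1])
    if abs(slope) * length < slope_resolution_ms:
        return "none"
    return "anterograde" if slope > 0 else "retrograde"


# ---------------------------------------------------------------------------
# Protocol execution
# ---------------------------------------------------------------------------


def _site_nodes(model: TissueModel, dictionary: LabelDictionary,
                label: str) -> tuple[int, ...]:
    idx = model.nodes_with_label(dictionary.code(label))
    if idx.size == 0:
        raise ValueError(f"no active nodes carry the label {label!r}")
    return tuple(int(i) for i in idx)


def run_sinus_beat(
    model: TissueModel,
    protocol: PacingProtocol | None = None,
    config: SolverConfig | None = None,
    dictionary: LabelDictionary | None = None,
    duration_ms: float = 120.0,
) -> SimulationResult:
    """One sinus-node-driven beat from rest (the S1 morphology)."""
    protocol = protocol or PacingProtocol()
    ldict = dictionary or default_label_dictionary()
    config = config or SolverConfig()
    config = replace(config, duration_ms=duration_ms)
    site = _site_nodes(model, ldict, protocol.site_label)
    stim = StimulusSpec(protocol.s1_amplitude, protocol.s1_duration_ms,
                        onset_ms=1.0, site=site)
    return run_simulation(model, [stim], config)


def run_s1_train(
    model: TissueModel,
    protocol: PacingProtocol | None = None,
    config: SolverConfig | None = None,
    dictionary: LabelDictionary | None = None,
    checkpoint_after_ms: float = 100.0,
) -> SimulationResult:
    """The S1 conditioning train; the run ends ``checkpoint_after_ms`` after
    the last S1 onset so its final state can seed every S2 branch."""
    protocol = protocol or PacingProtocol()
    ldict = dictionary or default_label_dictionary()
    site = _site_nodes(model, ldict, protocol.site_label)
    last_onset = 1.0 + (protocol.s1_count - 1) * protocol.s1_cycle_ms
    duration = last_onset + checkpoint_after_ms
    config = config or SolverConfig()
    config = replace(config, duration_ms=duration)
    stimuli = [StimulusSpec(protocol.s1_amplitude, protocol.s1_duration_ms,
                            onset_ms=1.0 + k * protocol.s1_cycle_ms, site=site)
               for k in range(protocol.s1_count)]
    res = run_simulation(model, stimuli, config)
    res.meta["last_s1_onset_ms"] = last_onset
    res.meta["checkpoint_t_ms"] = duration
    return res


def _s2_branch(model, protocol, config, site, s1_res, s2):
    last_onset = s1_res.meta["last_s1_onset_ms"]
    t_ck = s1_res.meta["checkpoint_t_ms"]
    s2_onset = last_onset + s2
    if s2_onset < t_ck:
        raise ValueError(f"S2 interval {s2} ms lies before the S1 checkpoint; "
                         "reduce checkpoint_after_ms")
    duration = s2_onset + protocol.observation_ms - t_ck
    cfg = replace(config, duration_ms=duration)
    stim = StimulusSpec(protocol.s2_amplitude, protocol.s2_duration_ms,
                        onset_ms=s2_onset, site=site)
    windows = np.array([[s2_onset, s2_onset + protocol.observation_ms]])
    return run_simulation(model, [stim], cfg,
                          initial_state=s1_res.final_state, t0=t_ck,
                          windows=windows)


@dataclass
class S1S2Result:
    """Results of a full S1-S2 sweep sharing one conditioning train."""

    s1_result: SimulationResult
    s2_results: dict[float, SimulationResult]
    protocol: PacingProtocol
    capture_table: dict[float, dict]
    min_capturing_s2: float | None


def run_s1s2_sweep(
    model: TissueModel,
    protocol: PacingProtocol | None = None,
    config: SolverConfig | None = None,
    dictionary: LabelDictionary | None = None,
    s1_result: SimulationResult | None = None,
) -> S1S2Result:
    """Run the conditioning train once, then branch one run per S2 interval
    from the checkpointed state (each branch is an independent premature
    beat of the same steady rhythm)."""
    protocol = protocol or PacingProtocol()
    ldict = dictionary or default_label_dictionary()
    config = config or SolverConfig()
    site = _site_nodes(model, ldict, protocol.site_label)
    if s1_result is None:
        s1_result = run_s1_train(model, protocol, config, ldict)
    s2_results = {float(s2): _s2_branch(model, protocol, config, site,
                                        s1_result, float(s2))
                  for s2 in protocol.s2_list}
    table = detect_block(s2_results, protocol.capture_fraction)
    return S1S2Result(s1_result, s2_results, protocol, table,
                      find_min_capturing_s2(table))


def find_capture_margin(
    model: TissueModel,
    sweep: S1S2Result,
    config: SolverConfig | None = None,
    dictionary: LabelDictionary | None = None,
    resolution_ms: float = 5.0,
) -> tuple[float, SimulationResult]:
    """Refine the capture boundary between the largest blocked and smallest
    capturing sweep members by bisection.

    The qualitative dual-pathway signature (fast-route-first nodal arrival
    with retrograde slow-pathway conduction) lives at the capture *margin*;
    a coarse sweep member can sit well above it.  Returns the smallest
    capturing interval at the requested resolution and its simulation.
    """
    protocol = sweep.protocol
    ldict = dictionary or default_label_dictionary()
    config = config or SolverConfig()
    site = _site_nodes(model, ldict, protocol.site_label)
    if sweep.min_capturing_s2 is None:
        raise ValueError("no sweep member captured; cannot bracket the margin")
    hi = sweep.min_capturing_s2
    blocked = [s2 for s2, row in sweep.capture_table.items()
               if not row["captured"] and s2 < hi]
    lo = max(blocked) if blocked else hi - 100.0
    best = sweep.s2_results[hi]
    while hi - lo > resolution_ms:
        mid = 0.5 * (lo + hi)
        res = _s2_branch(model, protocol, config, site, sweep.s1_result, mid)
        frac = float(np.mean(np.isfinite(res.activation[0])))
        if frac >= protocol.capture_fraction:
            hi, best = mid, res
        else:
            lo = mid
    return float(hi), best


def detect_block(
    s2_results: Mapping[float, SimulationResult],
    capture_fraction: float = 0.9,
) -> dict[float, dict]:
    """Per-S2 capture table: fraction of active nodes activated in the S2
    window and whether that beat captured the tissue."""
    table: dict[float, dict] = {}
    for s2, res in sorted(s2_results.items()):
        frac = float(np.mean(np.isfinite(res.activation[0])))
        table[float(s2)] = {"activated_fraction": frac,
                            "captured": bool(frac >= capture_fraction)}
    return table


def find_min_capturing_s2(capture_table: Mapping[float, dict]) -> float | None:
    """Smallest sweep member whose S2 beat captured; None if none did."""
    capt = [s2 for s2, row in sorted(capture_table.items()) if row["captured"]]
    return float(capt[0]) if capt else None


def run_repeated_pacing(
    model: TissueModel,
    interval_ms: float,
    n_stimuli: int = 12,
    protocol: PacingProtocol | None = None,
    config: SolverConfig | None = None,
    dictionary: LabelDictionary | None = None,
    s1_result: SimulationResult | None = None,
) -> dict:
    """Sustained fast pacing at a fixed coupling interval after the S1
    conditioning train; returns the per-stimulus capture record and the
    stimulus : activation ratio (2.0 means 2:1)."""
    protocol = protocol or PacingProtocol()
    ldict = dictionary or default_label_dictionary()
    config = config or SolverConfig()
    site = _site_nodes(model, ldict, protocol.site_label)
    if s1_result is None:
        s1_result = run_s1_train(model, protocol, config, ldict)
    last_onset = s1_result.meta["last_s1_onset_ms"]
    t_ck = s1_result.meta["checkpoint_t_ms"]
    onsets = [last_onset + k * interval_ms for k in range(1, n_stimuli + 1)]
    if onsets[0] < t_ck:
        raise ValueError("pacing interval lies before the S1 checkpoint")
    stimuli = [StimulusSpec(protocol.s2_amplitude, protocol.s2_duration_ms,
                            onset_ms=on, site=site) for on in onsets]
    windows = np.array([[on, on + interval_ms] for on in onsets])
    duration = onsets[-1] + interval_ms - t_ck
    cfg = replace(config, duration_ms=duration)
    res = run_simulation(model, stimuli, cfg,
                         initial_state=s1_result.final_state, t0=t_ck,
                         windows=windows)
    fracs = np.mean(np.isfinite(res.activation), axis=1)
    captured = fracs >= protocol.capture_fraction
    n_capt = int(captured.sum())
    ratio = float(n_stimuli / n_capt) if n_capt else float("inf")
    return {
        "interval_ms": float(interval_ms),
        "n_stimuli": n_stimuli,
        "n_captured": n_capt,
        "ratio": ratio,
        "captured": captured.tolist(),
        "activated_fractions": fracs.tolist(),
        "result": res,
    }
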