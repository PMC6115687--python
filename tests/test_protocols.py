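"""Pacing-protocol analysis operators on light-weight inputs.

The heavy S1-S2 runs live in session fixtures and are asserted in the
acceptance suite; here the analysis operators are exercised on synthetic
activation maps and small purpose-built geometries.
"""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atriasim import protocols, tissue
from atriasim.cells import StimulusSpec
from atriasim.phantoms import default_label_dictionary
from atriasim.protocols import (ActivationMap, PacingProtocol,
                                compute_activation_map, detect_block,
                                find_min_capturing_s2, isochrones,
                                pathway_arrival, propagation_direction)
from atriasim.solver import SolverConfig, run_simulation
from atriasim.volumes import LabelVolume, OrientationField


class TestProtocolValidation:
    def test_sweep_must_be_sorted(self):
        with pytest.raises(ValueError, match="sorted"):
            PacingProtocol(s2_list=(300.0, 250.0))

    def test_s2_bounded_by_cycle_length(self):
        with pytest.raises(ValueError):
            PacingProtocol(s2_list=(250.0, 450.0), s1_cycle_ms=400.0)

    def test_at_least_one_s1(self):
        with pytest.raises(ValueError):
            PacingProtocol(s1_count=0)


class TestActivationMapsAndIsochrones:
    def test_quiescent_beat_all_nan(self):
        model = tissue.strand_model(length_mm=5.0)
        cfg = SolverConfig(duration_ms=20.0)
        res = run_simulation(model, [], cfg)
        amap = compute_activation_map(res, 0, model)
        assert amap.nan_fraction == 1.0
        bands, n = isochrones(amap, 5.0)
        assert n == 0 and np.all(bands == -1)

    def test_planar_wave_activation_affine_in_distance(self):
        model = tissue.strand_model(length_mm=20.0, d_l=0.18583)
        cfg = SolverConfig(duration_ms=50.0)
        stim = StimulusSpec(20.0, 2.0, 1.0, site=tuple(range(8)))
        res = run_simulation(model, [stim], cfg)
        amap = compute_activation_map(res, 0, model)
        x = model.coords[:, 0] * model.spacing_mm
        sel = (x > 4.0) & (x < 16.0) & np.isfinite(amap.times)
        coef = np.polyfit(x[sel], amap.times[sel], 1)
        resid = amap.times[sel] - np.polyval(coef, x[sel])
        assert np.abs(resid).max() < 0.5  # ms

    def test_rethresholding_shifts_times_below_one_ms(self):
        """A healthy upstroke crosses -40 and -30 mV almost simultaneously."""
        model = tissue.strand_model(length_mm=10.0, d_l=0.18583)
        stim = [StimulusSpec(20.0, 2.0, 1.0, site=tuple(range(8)))]
        t40 = run_simulation(model, stim, SolverConfig(duration_ms=30.0))
        t30 = run_simulation(model, stim, SolverConfig(
            duration_ms=30.0, activation_threshold_mv=-30.0))
        d = t30.activation[0] - t40.activation[0]
        assert np.nanmax(np.abs(d)) < 1.0

    def test_isochrone_bands_partition_activated_nodes(self):
        times = np.array([np.nan, 0.0, 3.0, 7.0, 12.0, 19.9])
        amap = ActivationMap(times, (0.0, 50.0), -40.0, 0.15)
        bands, n = isochrones(amap, 5.0)
        assert n == 4  # ceil(19.9 / 5)
        assert bands[0] == -1
        assert list(bands[1:]) == [0, 0, 1, 2, 3]

    def test_single_band_when_interval_exceeds_spread(self):
        amap = ActivationMap(np.array([2.0, 3.0, 4.0]), (0.0, 10.0), -40.0, 0.15)
        bands, n = isochrones(amap, 50.0)
        assert n == 1 and set(bands) == {0}

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.0, 200.0), min_size=2, max_size=40),
           st.floats(0.5, 60.0))
    def test_isochrone_partition_property(self, times, interval):
        amap = ActivationMap(np.asarray(times), (0.0, 250.0), -40.0, 0.15)
        bands, n = isochrones(amap, interval)
        assert bands.min() >= 0 and bands.max() < n
        span = max(times) - min(times)
        assert n == max(1, int(np.ceil(span / interval))) or span == 0


def _two_route_geometry(len_a_vox=60, len_b_vox=60):
    """A symmetric Y: SN patch feeding two straight horizontal bundles that
    reconverge on a node patch; route labels slow/fast."""
    ldict = default_label_dictionary()
    nx = max(len_a_vox, len_b_vox) + 14
    lab = np.zeros((nx, 17, 1), np.int16)
    lab[2:6, 2:15, 0] = ldict.code("sinus_node")
    lab[6:6 + len_a_vox, 2:5, 0] = ldict.code("slow_pathway")
    lab[6:6 + len_b_vox, 12:15, 0] = ldict.code("fast_pathway_septal_bundle")
    x_node = 6 + max(len_a_vox, len_b_vox)
    lab[x_node:x_node + 4, 2:15, 0] = ldict.code("compact_AV_node")
    # connect route ends into the node patch
    lab[6 + len_a_vox:x_node, 2:5, 0] = ldict.code("slow_pathway")
    lab[6 + len_b_vox:x_node, 12:15, 0] = ldict.code("fast_pathway_septal_bundle")
    vec = np.zeros(lab.shape + (3,))
    vec[..., 0] = 1.0
    orient = OrientationField(np.where((lab > 0)[..., None], vec, 0.0),
                              (lab > 0).astype(float), 0.15)
    model = tissue.build_tissue_model(LabelVolume(lab, 0.15), orient,
                                      d_l=0.18583)
    h = 0.15
    routes = {}
    for name, label, y in (("slow", "slow_pathway", 3.5),
                           ("fast", "fast_pathway_septal_bundle", 13.5)):
        xs = np.arange(2.0, (x_node + 2) * h, 0.05)
        pts = np.stack([xs, np.full_like(xs, y * h)], axis=1)
        tan = np.tile([1.0, 0.0], (len(xs), 1))
        routes[name] = {"labels": [label], "points": pts, "tangents": tan,
                        "arclength": xs - xs[0],
                        "length_mm": float(xs[-1] - xs[0])}
    return model, routes, ldict


class TestPathwayAnalysis:
    def test_symmetric_routes_arrive_simultaneously(self):
        model, routes, ldict = _two_route_geometry()
        sn = model.nodes_with_label(ldict.code("sinus_node"))
        stim = StimulusSpec(30.0, 2.0, 1.0, site=tuple(int(i) for i in sn))
        res = run_simulation(model, [stim], SolverConfig(duration_ms=40.0))
        amap = compute_activation_map(res, 0, model)
        rep = pathway_arrival(amap, model, routes, ldict)
        assert abs(rep.fast_minus_slow_ms) < 1.0
        assert rep.directions["slow"] == "anterograde"
        assert rep.directions["fast"] == "anterograde"

    def test_shorter_route_arrives_first_on_avsd_geometry(self, sinus_beat,
                                                          avsd_model,
                                                          avsd_geometry):
        """Route length ordering slow < fast < annulus translates into the
        same nodal arrival ordering for a sinus-driven beat."""
        amap = compute_activation_map(sinus_beat, 0, avsd_model)
        rep = pathway_arrival(amap, avsd_model, avsd_geometry.routes)
        assert rep.order == ["slow", "fast", "annulus"]
        assert rep.fast_minus_slow_ms > 0.0
        assert rep.arrivals["annulus"] > rep.arrivals["fast"]

    def test_direction_trivials_on_synthetic_times(self, avsd_model,
                                                   avsd_geometry):
        route = avsd_geometry.routes["fast"]
        ldict = avsd_geometry.dictionary
        idx, s = protocols._route_samples(avsd_model, route, ldict)
        times = np.full(avsd_model.n_nodes, np.nan)
        times[idx] = 5.0 + 1.5 * s
        amap = ActivationMap(times, (0.0, 100.0), -40.0, 0.15)
        assert propagation_direction(amap, avsd_model, route, ldict) == \
            "anterograde"
        times[idx] = 80.0 - 1.5 * s
        amap = ActivationMap(times, (0.0, 100.0), -40.0, 0.15)
        assert propagation_direction(amap, avsd_model, route, ldict) == \
            "retrograde"
        times[idx] = 12.0
        amap = ActivationMap(times, (0.0, 100.0), -40.0, 0.15)
        assert propagation_direction(amap, avsd_model, route, ldict) == "none"

    def test_blocked_route_reports_nan_arrival(self, avsd_model, avsd_geometry):
        """A route whose distal half never activates has no nodal arrival."""
        route = avsd_geometry.routes["slow"]
        ldict = avsd_geometry.dictionary
        idx, s = protocols._route_samples(avsd_model, route, ldict)
        times = np.full(avsd_model.n_nodes, np.nan)
        prox = s < 4.0
        times[idx[prox]] = 5.0 + 1.5 * s[prox]
        amap = ActivationMap(times, (0.0, 100.0), -40.0, 0.15)
        rep = pathway_arrival(amap, avsd_model, avsd_geometry.routes, ldict)
        assert np.isnan(rep.arrivals["slow"])
        assert "slow" not in rep.order


class TestCaptureTables:
    def _fake_result(self, frac, n=100):
        class R:
            activation = np.full((1, n), np.nan)
        r = R()
        r.activation[0, : int(round(frac * n))] = 1.0
        return r

    def test_detect_block_thresholds_fraction(self):
        table = detect_block({250.0: self._fake_result(0.1),
                              300.0: self._fake_result(0.95),
                              400.0: self._fake_result(1.0)})
        assert not table[250.0]["captured"]
        assert table[300.0]["captured"] and table[400.0]["captured"]

    def test_min_capturing_s2(self):
        table = {250.0: {"captured": False, "activated_fraction": 0.1},
                 300.0: {"captured": True, "activated_fraction": 1.0},
                 400.0: {"captured": True, "activated_fraction": 1.0}}
        assert find_min_capturing_s2(table) == 300.0

    def test_all_capturing_returns_sweep_minimum(self):
        table = {s: {"captured": True, "activated_fraction": 1.0}
                 for s in (250.0, 300.0)}
        assert find_min_capturing_s2(table) == 250.0

    def test_none_capturing_returns_none(self):
        table = {s: {"captured": False, "activated_fraction": 0.0}
                 for s in (250.0, 300.0)}
        assert find_min_capturing_s2(table) is None
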