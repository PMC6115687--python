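"""Shared fixtures.

The expensive objects — the calibrated diffusion coefficient, the default
AVSD geometry and tissue model, the S1 conditioning train and the S1-S2
sweep built on it — are session-scoped so the protocol-level tests and the
acceptance suite share one computation of each.
"""
from __future__ import annotations

import numpy as np
import pytest

from atriasim import phantoms, protocols, solver, tissue


@pytest.fixture(scope="session")
def calibration() -> solver.CalibrationResult:
    """d_l calibrated so an RA strand at h=0.15 mm conducts at 68.2 cm/s."""
    return solver.calibrate_diffusion()


@pytest.fixture(scope="session")
def avsd_geometry() -> phantoms.AVSDGeometry:
    return phantoms.make_avsd_atria()


@pytest.fixture(scope="session")
def avsd_model(avsd_geometry, calibration) -> tissue.TissueModel:
    return tissue.build_tissue_model(avsd_geometry.labels,
                                     avsd_geometry.orientation,
                                     d_l=calibration.d_l)


@pytest.fixture(scope="session")
def sinus_beat(avsd_model):
    """One sinus-node beat from rest on the default geometry."""
    return protocols.run_sinus_beat(avsd_model)


@pytest.fixture(scope="session")
def s1_train(avsd_model):
    return protocols.run_s1_train(avsd_model)


@pytest.fixture(scope="session")
def s1s2_sweep(avsd_model, s1_train) -> protocols.S1S2Result:
    return protocols.run_s1s2_sweep(avsd_model, s1_result=s1_train)


@pytest.fixture(scope="session")
def capture_margin(avsd_model, s1s2_sweep):
    """(margin interval ms, margin beat re-run with a 480 ms observation
    window and 10 ms voltage snapshots so post-beat recovery is visible)."""
    from dataclasses import replace

    margin_s2, _ = protocols.find_capture_margin(avsd_model, s1s2_sweep)
    proto_long = replace(s1s2_sweep.protocol, observation_ms=480.0)
    cfg = solver.SolverConfig(snapshot_interval_ms=10.0)
    site = protocols._site_nodes(avsd_model, phantoms.default_label_dictionary(),
                                 proto_long.site_label)
    res = protocols._s2_branch(avsd_model, proto_long, cfg, site,
                               s1s2_sweep.s1_result, margin_s2)
    return margin_s2, res


@pytest.fixture(scope="session")
def pacing_250(avsd_model, s1_train):
    return protocols.run_repeated_pacing(avsd_model, 250.0, 12,
                                         s1_result=s1_train)


@pytest.fixture(scope="session")
def parallel_phantom():
    spec = phantoms.FiberPhantomSpec(pattern="parallel", grid_shape=(48, 48, 48),
                                     noise_sd=0.0, seed=11)
    return phantoms.make_fiber_phantom(spec), spec


def activation_map_of(result, beat, model):
    return protocols.compute_activation_map(result, beat, model)


def pathway_report(result, beat, model, geometry):
    amap = protocols.compute_activation_map(result, beat, model)
    return protocols.pathway_arrival(amap, model, geometry.routes)
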