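"""Staged pipeline: geometry -> tissue model -> CV calibration -> S1-S2
simulation -> analysis, with digest-based caching per stage.

Each stage writes its outputs plus a ``stage.json`` carrying a digest of
the configuration it depends on (its own section plus all upstream
digests).  Re-running with an unchanged configuration is a no-op; changing
e.g. the S2 sweep re-runs only the simulate and analyze stages.  The output
directory carries exactly one run manifest.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as aio
from . import phantoms, protocols, solver, tissue

__all__ = ["default_config", "load_config", "pipeline_run"]


def default_config() -> dict:
    """Layered configuration defaults (units are explicit in field names)."""
    return {
        "seed": 0,
        "geometry": {},              # AVSDGeometrySpec overrides
        "tissue": {
            "ratio": 8.0,
            "block_zone_enabled": True,
            "model_id": "atrial_detailed",
            "d_l": None,             # None -> take the calibrated value
        },
        "calibration": {
            "enabled": True,
            "target_cv_cm_s": 68.2,
            "tol_cv_cm_s": 0.1,
        },
        "solver": {
            "dt_ms": 0.02,
            "output_interval_ms": 1.0,
        },
        "protocol": {},              # PacingProtocol overrides
        "analysis": {
            "isochrone_interval_ms": 5.0,
        },
    }


def load_config(path_or_dict) -> dict:
    """defaults < file/dict; unknown keys are rejected."""
    cfg = default_config()
    if path_or_dict is None:
        return cfg
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    for key, val in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(cfg[key], dict):
            cfg[key] = {**cfg[key], **(val or {})}
        else:
            cfg[key] = val
    return cfg


def _stage_dir(outdir: Path, name: str) -> Path:
    d = outdir / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _stage_cached(stage: Path, digest: str) -> bool:
    meta = stage / "stage.json"
    if not meta.exists():
        return False
    try:
        saved = json.loads(meta.read_text())
    except json.JSONDecodeError:
        return False
    if saved.get("digest") != digest:
        return False
    return all((stage / f).exists() for f in saved.get("outputs", []))


def _stage_done(stage: Path, digest: str, outputs: list[str]) -> None:
    (stage / "stage.json").write_text(
        json.dumps({"digest": digest, "outputs": outputs}, indent=2))


def pipeline_run(config=None, outdir="pipeline_out", force: bool = False
                 ) -> aio.RunManifest:
    """Run (or resume) the full pipeline; returns the run manifest.

    Stages and their cache keys:

    * ``geometry``  — AVSD label volume + orientation (geometry section)
    * ``build``     — tissue-model summary (geometry + tissue sections)
    * ``calibrate`` — longitudinal diffusion coefficient for the target CV
    * ``simulate``  — S1 train + S2 sweep activation times
    * ``analyze``   — capture table, pathway reports, VTK activation maps
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages_run: dict[str, str] = {}

    # --- geometry (cheap; always reconstructed in memory) -----------------
    g_digest = aio.config_digest({"geometry": cfg["geometry"]})
    gdir = _stage_dir(outdir, "geometry")
    spec = phantoms.AVSDGeometrySpec(**cfg["geometry"])
    geom = phantoms.make_avsd_atria(spec)
    if force or not _stage_cached(gdir, g_digest):
        aio.write_volume(geom.labels, gdir / "labels.nii.gz")
        aio.write_orientation(geom.orientation, gdir / "orientation.nii.gz")
        (gdir / "labels.json").write_text(
            json.dumps(geom.dictionary.to_json_dict(), indent=2))
        _stage_done(gdir, g_digest,
                    ["labels.nii.gz", "orientation.nii.gz", "labels.json"])
        stages_run["geometry"] = "run"
    else:
        stages_run["geometry"] = "cached"

    # --- calibration ------------------------------------------------------
    cal_digest = aio.config_digest({"calibration": cfg["calibration"],
                                    "solver": cfg["solver"],
                                    "model_id": cfg["tissue"]["model_id"]})
    cdir = _stage_dir(outdir, "calibrate")
    cal_path = cdir / "calibration.json"
    if cfg["tissue"]["d_l"] is not None or not cfg["calibration"]["enabled"]:
        d_l = float(cfg["tissue"]["d_l"] or 0.1)
        stages_run["calibrate"] = "skipped"
    elif not force and _stage_cached(cdir, cal_digest):
        d_l = float(json.loads(cal_path.read_text())["d_l"])
        stages_run["calibrate"] = "cached"
    else:
        scfg = solver.SolverConfig(dt_ms=cfg["solver"]["dt_ms"],
                                   duration_ms=120.0,
                                   output_interval_ms=1.0)
        cal = solver.calibrate_diffusion(
            target_cv=cfg["calibration"]["target_cv_cm_s"],
            h=spec.voxel_size_mm,
            ratio=cfg["tissue"]["ratio"],
            config=scfg,
            tol_cv=cfg["calibration"]["tol_cv_cm_s"])
        cal_path.write_text(json.dumps(cal.as_dict(), indent=2))
        _stage_done(cdir, cal_digest, ["calibration.json"])
        d_l = cal.d_l
        stages_run["calibrate"] = "run"

    # --- tissue model -----------------------------------------------------
    b_digest = aio.config_digest({"geometry": cfg["geometry"],
                                  "tissue": cfg["tissue"], "d_l": d_l})
    bdir = _stage_dir(outdir, "build")
    model = tissue.build_tissue_model(
        geom.labels, geom.orientation, d_l=d_l,
        ratio=cfg["tissue"]["ratio"],
        block_zone_enabled=cfg["tissue"]["block_zone_enabled"],
        model_id=cfg["tissue"]["model_id"])
    if force or not _stage_cached(bdir, b_digest):
        model.save(bdir / "model.h5")
        model.class_counts().to_csv(bdir / "class_counts.csv", index=False)
        _stage_done(bdir, b_digest, ["model.h5", "class_counts.csv"])
        stages_run["build"] = "run"
    else:
        stages_run["build"] = "cached"

    # --- simulate ---------------------------------------------------------
    s_digest = aio.config_digest({"build": b_digest,
                                  "protocol": cfg["protocol"],
                                  "solver": cfg["solver"]})
    sdir = _stage_dir(outdir, "simulate")
    proto = protocols.PacingProtocol(**cfg["protocol"])
    scfg = solver.SolverConfig(**cfg["solver"])
    sim_npz = sdir / "activation.npz"
    if not force and _stage_cached(sdir, s_digest):
        stages_run["simulate"] = "cached"
        dat = np.load(sim_npz)
        s1_act, s1_win = dat["s1_activation"], dat["s1_windows"]
        s2_act = {float(s2): dat[f"s2_{s2:g}"] for s2 in proto.s2_list}
        s2_win = {float(s2): dat[f"s2win_{s2:g}"] for s2 in proto.s2_list}
    else:
        sweep = protocols.run_s1s2_sweep(model, proto, scfg)
        s1_act, s1_win = sweep.s1_result.activation, sweep.s1_result.windows
        s2_act = {s2: r.activation for s2, r in sweep.s2_results.items()}
        s2_win = {s2: r.windows for s2, r in sweep.s2_results.items()}
        arrays = {"s1_activation": s1_act, "s1_windows": s1_win}
        for s2 in proto.s2_list:
            arrays[f"s2_{s2:g}"] = s2_act[float(s2)]
            arrays[f"s2win_{s2:g}"] = s2_win[float(s2)]
        np.savez_compressed(sim_npz, **arrays)
        _stage_done(sdir, s_digest, ["activation.npz"])
        stages_run["simulate"] = "run"

    # --- analyze ----------------------------------------------------------
    a_digest = aio.config_digest({"simulate": s_digest,
                                  "analysis": cfg["analysis"]})
    adir = _stage_dir(outdir, "analyze")
    if not force and _stage_cached(adir, a_digest):
        stages_run["analyze"] = "cached"
    else:
        thr = scfg.activation_threshold_mv
        capture = {}
        for s2 in proto.s2_list:
            frac = float(np.mean(np.isfinite(s2_act[float(s2)][0])))
            capture[float(s2)] = {"activated_fraction": frac,
                                  "captured": frac >= proto.capture_fraction}
        min_s2 = protocols.find_min_capturing_s2(capture)

        def amap_of(act_row, window):
            return protocols.ActivationMap(act_row, (float(window[0]),
                                                     float(window[1])),
                                           thr, model.spacing_mm)

        last_s1 = amap_of(s1_act[-1], s1_win[-1])
        rep_s1 = protocols.pathway_arrival(last_s1, model, geom.routes)
        report: dict[str, Any] = {
            "capture_table": capture,
            "min_capturing_s2_ms": min_s2,
            "s1_beat": {
                "arrivals_ms": rep_s1.arrivals,
                "order": rep_s1.order,
                "fast_minus_slow_ms": rep_s1.fast_minus_slow_ms,
                "directions": rep_s1.directions,
            },
        }
        if min_s2 is not None:
            amap2 = amap_of(s2_act[min_s2][0], s2_win[min_s2][0])
            rep2 = protocols.pathway_arrival(amap2, model, geom.routes)
            report["min_s2_beat"] = {
                "arrivals_ms": rep2.arrivals,
                "order": rep2.order,
                "fast_minus_slow_ms": rep2.fast_minus_slow_ms,
                "directions": rep2.directions,
            }
        (adir / "report.json").write_text(
            json.dumps(report, indent=2, default=lambda x: None
                       if isinstance(x, float) and not np.isfinite(x) else x))
        aio.write_vtk_activation(
            s1_act[-1], model, adir / "s1_activation.vtk",
            isochrone_interval_ms=cfg["analysis"]["isochrone_interval_ms"])
        _stage_done(adir, a_digest, ["report.json", "s1_activation.vtk"])
        stages_run["analyze"] = "run"

    manifest = aio.RunManifest(
        config=cfg, seed=cfg.get("seed"),
        extra={"stages": stages_run, "d_l": d_l,
               "geometry_spec": asdict(spec) if hasattr(spec, "__dict__")
               else str(spec)})
    manifest.write(outdir)
    return manifest
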