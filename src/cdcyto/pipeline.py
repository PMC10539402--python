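"""End-to-end pipeline: simulate -> QC -> detect -> track -> measure -> fit
(-> classify), with a JSON manifest of stage outputs, timings and provenance.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autolabel, io, measure, rheology, simulate, stratify, tracking
from .device import build_geometry, creep_window, detection_regions
from .errors import CdcytoError

log = logging.getLogger("cdcyto")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (all stages)."""

    out_dir: str = "cdcyto_run"
    seed: int = 0
    n_cells: int = 30
    geometry: dict = field(default_factory=lambda: {"n_groups": 1, "constrictions_per_group": 9, "pixel_size": 1.0})
    imaging: dict = field(default_factory=dict)
    populations: list = field(default_factory=list)  # PopulationSpec kwargs
    tracker: dict = field(default_factory=dict)
    rheology: dict = field(default_factory=dict)
    features: list = field(default_factory=lambda: ["passage_time_s", "a_cell_um2", "area_in_constriction_um2"])
    n_stalled: int = 0
    qc_stall_seconds: float = 3.0
    write_frames: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls(**io.load_config(path))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the manifest dict.

    Any stage failure aborts with the stage name and cause; partial outputs
    written so far are retained.  A QC "discard" verdict stops the run after
    the QC stage with the verdict logged in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    # hash the scientific parameters only: the same analysis written to a
    # different directory is the same run
    cfg_hash = io.config_hash({k: v for k, v in cfg_dict.items() if k != "out_dir"})
    manifest = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "config": cfg_dict,
        "stages": [],
    }

    def _stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                info = fn() or {}
            except CdcytoError as exc:
                manifest["stages"].append({"name": name, "status": "failed", "error": str(exc)})
                _write_manifest(out, manifest)
                raise
            info.update({"name": name, "status": "ok", "seconds": round(time.perf_counter() - t0, 3)})
            manifest["stages"].append(info)
            log.info("stage %s done in %.2fs", name, info["seconds"])
            return info

        return deco

    geom = build_geometry(config.geometry)
    imaging = simulate.ImagingModel(**config.imaging)
    specs = (
        [simulate.PopulationSpec(**kw) for kw in config.populations]
        if config.populations
        else simulate.default_population_specs()
    )
    state: dict = {}

    @_stage("simulate")
    def _sim():
        frames, truth, _ = simulate.simulate_video(
            specs, config.n_cells, geom=geom, imaging=imaging,
            seed=config.seed, n_stalled=config.n_stalled,
        )
        state["frames"], state["truth"] = frames, truth
        truth.cells.to_csv(out / "truth_cells.csv", index=False)
        truth.objects.to_csv(out / "truth_objects.csv", index=False)
        if config.write_frames:
            io.write_frames(frames, out / "frames")
        return {"n_frames": len(frames), "n_cells": len(truth.cells)}

    @_stage("detect")
    def _detect():
        state["detections"] = autolabel.detect_frames(state["frames"])
        n = sum(len(d) for d in state["detections"])
        return {"n_detections": n}

    @_stage("track")
    def _track():
        params = tracking.TrackerParams(**config.tracker)
        state["tracks"] = tracking.track_detections(state["detections"], params)
        tracking.tracks_to_frame(state["tracks"], run_id=cfg_hash).to_csv(
            out / "tracks.csv", index=False
        )
        return {"n_tracks": len(state["tracks"])}

    @_stage("qc")
    def _qc():
        # dedicated detection pass against the *first* frame: a fouling object
        # that sits still for most of the video is absorbed into the median
        # background and would be invisible to the main detector
        qc_dets = autolabel.detect_frames(state["frames"], reference=state["frames"][0])
        qc_tracks = tracking.track_detections(qc_dets)
        res = stratify.fouling_qc(
            qc_tracks, geom, imaging.fps,
            stall_frames_threshold=int(config.qc_stall_seconds * imaging.fps),
        )
        state["qc"] = res
        return {"verdict": res.verdict, "fouled": res.fouled_constrictions}

    if state["qc"].verdict == "discard":
        manifest["verdict"] = "discard"
        _write_manifest(out, manifest)
        log.warning("QC verdict: discard; pipeline stopped")
        return manifest

    @_stage("measure")
    def _measure():
        records = measure.measure_cells(
            state["frames"], state["tracks"], geom, imaging.fps
        )
        state["records"] = records
        io.write_records(records, out / "records.csv", seed=config.seed, cfg_hash=cfg_hash)
        return {"n_records": len(records), "n_censored": int(records["censored"].sum())}

    @_stage("fit")
    def _fit():
        params = rheology.StiffnessModelParams(**config.rheology)
        rec = state["records"]
        ok = rec.dropna(subset=["t_creep_s", "a_cell_um2"])
        beta_best, fits = rheology.select_beta(
            ok["t_creep_s"].to_numpy(), ok["a_cell_um2"].to_numpy(), params
        )
        rec["c1_per_cell"] = rheology.c1_per_cell(
            rec["t_creep_s"].to_numpy(), rec["a_cell_um2"].to_numpy(), beta_best, params.c2
        )
        io.write_records(rec, out / "records.csv", seed=config.seed, cfg_hash=cfg_hash)
        fit = fits[beta_best]
        result = {
            "beta_best": beta_best,
            "c1_hat": fit.c1_hat,
            "r_squared": fit.r_squared,
            "n_cells": fit.n_cells,
            "elastic_modulus_pa": rheology.elastic_modulus(fit.c1_hat, beta_best, params.delta_p_bar),
            "per_beta_r2": {str(b): f.r_squared for b, f in fits.items()},
        }
        (out / "fit.json").write_text(json.dumps(result, indent=2))
        return {"beta_best": beta_best, "c1_hat": fit.c1_hat, "r_squared": fit.r_squared}

    manifest["verdict"] = "keep"
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict):
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
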