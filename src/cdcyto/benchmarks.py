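"""Seeded synthetic benchmarks used by the test suite and the acceptance script.

Each function runs the package end to end on simulator output under the
default study conditions and reports scalar metrics:

* :func:`end_to_end_metrics` — full video -> detection -> tracking ->
  measurement, scored against the simulator truth (identity switches,
  creep-time and cell-area accuracy);
* :func:`beta_recovery` — group-fit recovery of (beta, c1) across the
  exponent grid from noisy forward-model draws;
* :func:`mixture_medians` — median per-cell c1 across stiff:soft mixture
  ratios (1:0, 9:1, 4:1, 1:4, 1:9, 0:1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import autolabel, measure, rheology, simulate, tracking
from .device import build_geometry

#: stiff:soft mixture series (fraction of the stiff population), matching the
#: pure / 9:1 / 4:1 / 1:4 / 1:9 / pure mixture design.
MIXTURE_STIFF_FRACTIONS = (1.0, 0.9, 0.8, 0.2, 0.1, 0.0)


def benchmark_geometry(n_lanes: int = 9):
    """Single-group geometry at 1 um/px used for rendered-video benchmarks.

    One group in the field of view mirrors the 10x-objective acquisition
    setting; 1 um/px keeps frames small while cells stay >= 13 px in radius.
    """
    return build_geometry(
        {
            "n_groups": 1,
            "constrictions_per_group": n_lanes,
            "pixel_size": 1.0,
            "entrance_x_um": 60.0,
        }
    )


def match_tracks_to_truth(
    tracks: list[tracking.Track],
    truth: simulate.SyntheticTruth,
    max_dist_px: float = 15.0,
) -> tuple[dict, int]:
    """Assign each track to a truth cell and count identity switches.

    Per frame, a track is matched to the nearest rendered truth object within
    ``max_dist_px``; a track whose matched truth id changes over its lifetime
    contributes one switch per change.  Returns
    (track_id -> majority truth cell_id, total switches).
    """
    by_frame: dict[int, tuple] = {}
    for f, grp in truth.objects.groupby("frame"):
        by_frame[int(f)] = (
            grp["cell_id"].to_numpy(),
            grp["cx"].to_numpy(),
            grp["cy"].to_numpy(),
        )
    assignment: dict[int, int] = {}
    switches = 0
    for t in tracks:
        ids_seen: list[int] = []
        for frame, _bbox, (cx, cy) in t.history:
            if frame not in by_frame:
                continue
            ids, xs, ys = by_frame[frame]
            d2 = (xs - cx) ** 2 + (ys - cy) ** 2
            j = int(np.argmin(d2))
            if d2[j] <= max_dist_px**2:
                ids_seen.append(int(ids[j]))
        if not ids_seen:
            continue
        arr = np.asarray(ids_seen)
        switches += int(np.sum(arr[1:] != arr[:-1]))
        vals, counts = np.unique(arr, return_counts=True)
        assignment[t.track_id] = int(vals[np.argmax(counts)])
    return assignment, switches


def end_to_end_metrics(seed: int = 1, n_cells: int = 50, n_lanes: int = 9) -> dict:
    """Full pipeline on one synthetic video, scored against truth.

    Default imaging noise; returns identity switches, track/cell counts and
    the fractions of non-censored cells whose measured creep time is within
    2/fps of truth and whose measured pre-entry area is within 5% of truth.
    """
    geom = benchmark_geometry(n_lanes)
    imaging = simulate.ImagingModel()
    frames, truth, _ = simulate.simulate_video(
        n_cells=n_cells, geom=geom, imaging=imaging, seed=seed
    )
    detections = autolabel.detect_frames(frames)
    tracks = tracking.track_detections(detections)
    records = measure.measure_cells(frames, tracks, geom, imaging.fps)

    assignment, switches = match_tracks_to_truth(tracks, truth)
    records = records.assign(
        cell_id=[assignment.get(tid, -1) for tid in records["track_id"]]
    )
    merged = records.merge(
        truth.cells[["cell_id", "t_creep", "area_um2"]], on="cell_id", how="inner"
    )
    ok = merged.dropna(subset=["t_creep_s"])
    tol = 2.0 / imaging.fps
    tcreep_ok = np.abs(ok["t_creep_s"] - ok["t_creep"]) <= tol + 1e-12
    area = merged.dropna(subset=["a_cell_um2"])
    area_ok = np.abs(area["a_cell_um2"] - area["area_um2"]) <= 0.05 * area["area_um2"]
    return {
        "n_true_cells": int(len(truth.cells)),
        "n_tracks": int(len(tracks)),
        "identity_switches": int(switches),
        "n_measured": int(len(ok)),
        "tcreep_within_2frames_frac": float(tcreep_ok.mean()) if len(ok) else np.nan,
        "acell_within_5pct_frac": float(area_ok.mean()) if len(area) else np.nan,
        "n_frames": int(len(frames)),
    }


def beta_recovery(
    n_cells: int = 300,
    noise: float = 0.05,
    n_seeds: int = 20,
    c1_true: float = 0.48,
    seed: int = 0,
    beta_grid=(0.1, 0.2, 0.3, 0.4, 0.5),
    c1_tol: float = 0.03,
) -> dict:
    """Parameter recovery of (beta, c1) by grid fitting.

    For each beta on the grid and each of ``n_seeds`` replicates: draw
    ``n_cells`` areas from the default size support, compute forward creep
    times with ``c1_true``, apply ``noise`` multiplicative lognormal-free
    noise (1 + N(0, noise)), and check that :func:`cdcyto.rheology.select_beta`
    returns the generating beta with c1_hat within ``c1_tol`` relative.

    Returns per-beta success fractions and the overall fraction.
    """
    rng = np.random.default_rng(seed)
    params = rheology.StiffnessModelParams(beta_grid=tuple(beta_grid))
    lo, hi = simulate.DEFAULT_AREA_RANGE
    per_beta: dict[float, float] = {}
    for beta in beta_grid:
        hits = 0
        for _ in range(n_seeds):
            areas = rng.uniform(lo, hi, size=n_cells)
            t = rheology.forward_creep_time(areas, c1_true, beta, params.c2)
            t_noisy = t * (1.0 + rng.normal(0.0, noise, size=n_cells))
            beta_hat, fits = rheology.select_beta(t_noisy, areas, params)
            if beta_hat == beta and abs(fits[beta_hat].c1_hat - c1_true) <= c1_tol * c1_true:
                hits += 1
        per_beta[float(beta)] = hits / n_seeds
    overall = float(np.mean(list(per_beta.values())))
    return {"per_beta": per_beta, "overall": overall}


def mixture_medians(
    seed: int = 0,
    n_per_group: int = 4000,
    noise: float = 0.05,
    stiff_fractions=MIXTURE_STIFF_FRACTIONS,
) -> dict:
    """Median per-cell c1 across the stiff:soft mixture series.

    Each mixture is sampled with exact fractions, creep times are taken from
    the forward model with multiplicative noise, and per-cell c1 is recovered
    by inversion at beta = 0.5.  As the soft fraction rises the median c1
    must fall.  ``n_per_group`` is sized so the closest adjacent pair of the
    series (9:1 vs 4:1, whose medians sit at the 44.4% and 37.5% quantiles of
    the stiff c1 distribution, a ~4% gap at geometric SD 1.25) is separated
    by about five standard errors of the median difference.
    """
    rng = np.random.default_rng(seed)
    c2 = rheology.DEFAULT_C2_UM
    medians = []
    for f_stiff in stiff_fractions:
        if f_stiff == 1.0:
            specs = [simulate.PopulationSpec("stiff", 1.0, 0.48)]
        elif f_stiff == 0.0:
            specs = [simulate.PopulationSpec("soft", 1.0, 0.12)]
        else:
            specs = simulate.default_population_specs(stiff_fraction=f_stiff)
        cells = simulate.sample_population(
            specs, n_per_group, seed=rng.integers(2**31), exact_fractions=True
        )
        t = np.array([c.t_creep for c in cells])
        a = np.array([c.area_um2 for c in cells])
        t_noisy = t * (1.0 + rng.normal(0.0, noise, size=len(t)))
        c1 = rheology.c1_per_cell(t_noisy, a, beta=0.5, c2=c2)
        medians.append(float(np.nanmedian(c1)))
    medians = list(medians)
    decreasing = all(a > b for a, b in zip(medians, medians[1:]))
    return {
        "stiff_fractions": list(stiff_fractions),
        "median_c1": medians,
        "strictly_decreasing": bool(decreasing),
    }
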