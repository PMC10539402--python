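"""Per-cell measurements from tracks + frames.

Turns identity-resolved tracks into one record per cell:

* region events — first/last frames with the centroid inside the entrance
  (blue) and exit (green) focal regions of its constriction;
* passage time — (last frame in exit region - first frame in entrance
  region) / fps;
* creep time — time for the centroid to traverse the creep window around the
  entrance plane;
* morphometrics — segmentation-based area, minimum-area enclosing rectangle
  sides H >= W, deformation index (H - W)/(H + W), equivalent diameter;
* A_cell — median area over the 3 frames immediately before the entrance
  event (the undeformed cell);
* area-in-constriction — median segmented area over frames with the centroid
  inside the constriction span.

Segmentation is classical by default (difference-from-reference thresholding,
reusing the autolabel primitives); any callable with the same
``(frame, bbox) -> mask`` contract can be plugged in for a neural backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label as cc_label

from .autolabel import abs_difference, background_reference, otsu_difference_threshold
from .device import CreepWindow, DetectionRegion, DeviceGeometry, detection_regions, creep_window
from .errors import AmbiguityError, DataIntegrityError, InputError
from .tracking import Track

RECORD_COLUMNS = [
    "track_id",
    "constriction_id",
    "group_label",
    "a_cell_um2",
    "area_in_constriction_um2",
    "h_um",
    "w_um",
    "deformation_index",
    "equivalent_diameter_um",
    "passage_time_s",
    "t_creep_s",
    "c1_per_cell",
    "censored",
    "flags",
]


@dataclass(frozen=True)
class RegionEvent:
    """A track's stay in one focal region: [first_frame, last_frame]."""

    track_id: int
    constriction_id: int
    kind: str  # "entrance" | "exit"
    first_frame: int
    last_frame: int


def assign_constriction(track: Track, geom: DeviceGeometry) -> int:
    """Lane assignment by nearest lane_y to the track's median centroid."""
    cy = float(np.median(track.centroids()[:, 1]))
    return geom.nearest_constriction(cy)


def region_events(
    tracks: list[Track], regions: list[DetectionRegion], geom: DeviceGeometry
) -> list[RegionEvent]:
    """First/last in-region frames per (track, region).

    Membership is tested on the track centroid; each track is only tested
    against the two regions of its assigned lane.  A centroid inside both
    regions of a lane at once means the regions overlap — a configuration
    problem surfaced as :class:`AmbiguityError`.
    """
    by_cid: dict[tuple, DetectionRegion] = {
        (r.constriction_id, r.kind): r for r in regions
    }
    events: list[RegionEvent] = []
    for t in tracks:
        cid = assign_constriction(t, geom)
        lane_regions = [by_cid.get((cid, "entrance")), by_cid.get((cid, "exit"))]
        lane_regions = [r for r in lane_regions if r is not None]
        frames_in: dict[str, list[int]] = {r.kind: [] for r in lane_regions}
        for frame, _bbox, (cx, cy) in t.history:
            hits = [r for r in lane_regions if r.contains(cx, cy)]
            if len(hits) > 1:
                raise AmbiguityError(
                    f"track {t.track_id} centroid inside {len(hits)} regions of "
                    f"constriction {cid} at frame {frame}; regions must not overlap"
                )
            if hits:
                frames_in[hits[0].kind].append(frame)
        for kind, fr in frames_in.items():
            if fr:
                events.append(RegionEvent(t.track_id, cid, kind, min(fr), max(fr)))
    return events


def passage_time(entrance_event: RegionEvent, exit_event: RegionEvent, fps: float) -> float:
    """Passage time (s): first frame in entrance to last frame in exit."""
    if entrance_event is None or exit_event is None:
        raise InputError("both entrance and exit events are required")
    if (
        entrance_event.track_id != exit_event.track_id
        or entrance_event.constriction_id != exit_event.constriction_id
    ):
        raise InputError("events must belong to the same track and constriction")
    dt = exit_event.last_frame - entrance_event.first_frame
    if dt <= 0:
        raise DataIntegrityError(
            f"non-positive passage interval ({dt} frames) for track "
            f"{entrance_event.track_id}"
        )
    return dt / fps


@dataclass(frozen=True)
class CreepResult:
    value: float | None  # seconds, None when censored
    reason: str = ""  # "", "entry_unobserved", "stalled"


def creep_time(
    track: Track,
    window: CreepWindow,
    fps: float,
    interpolate: bool = False,
    smooth_window: int = 3,
) -> CreepResult:
    """Creep-stage duration from centroid crossings of the window boundaries.

    Time between the first frame with centroid-x >= x_start and the first
    frame with centroid-x >= x_end.  ``interpolate`` refines both crossings
    by linear sub-frame interpolation (off by default: one timestamp per
    frame).  Censored when the track starts inside the window (entry
    unobserved) or never reaches the window end (stalled).

    The centroid trajectory is de-jittered by a running median of
    ``smooth_window`` samples before crossing detection: near the window end
    the cell advances a fraction of a pixel per frame, so sub-pixel centroid
    noise would otherwise shift the detected crossing by several frames.  A
    running median is exact on monotone data (no bias); 1 disables it.
    """
    frames = track.frames()
    xs = track.centroids()[:, 0]
    if smooth_window > 1 and len(xs) >= smooth_window:
        from scipy.ndimage import median_filter

        xs = median_filter(xs, size=smooth_window, mode="nearest")
    if xs[0] >= window.x_start:
        return CreepResult(None, "entry_unobserved")
    in_idx = np.nonzero(xs >= window.x_start)[0]
    out_idx = np.nonzero(xs >= window.x_end)[0]
    if len(out_idx) == 0:
        return CreepResult(None, "stalled")
    i0, i1 = int(in_idx[0]), int(out_idx[0])
    if interpolate:
        t0 = _interp_crossing(frames, xs, i0, window.x_start)
        t1 = _interp_crossing(frames, xs, i1, window.x_end)
        return CreepResult((t1 - t0) / fps)
    return CreepResult((int(frames[i1]) - int(frames[i0])) / fps)


def _interp_crossing(frames, xs, i, x_target) -> float:
    if i == 0 or xs[i] == xs[i - 1]:
        return float(frames[i])
    frac = (x_target - xs[i - 1]) / (xs[i] - xs[i - 1])
    return float(frames[i - 1]) + frac * (float(frames[i]) - float(frames[i - 1]))


# ---------------------------------------------------------------------------
# segmentation + morphometrics
# ---------------------------------------------------------------------------

def segment_crop(
    frame: np.ndarray,
    reference: np.ndarray,
    bbox,
    threshold: float,
    crop_size: int = 200,
    smooth_sigma: float = 1.0,
) -> np.ndarray | None:
    """Segment the cell in a square crop centered on ``bbox``.

    Difference-from-reference thresholding (signed difference smoothed by
    ``smooth_sigma`` to stabilize the contour), then the connected component
    at (or nearest to) the crop center.  Returns the mask in full-frame
    coordinates, or None on segmentation failure (empty mask).
    """
    h, w = frame.shape[:2]
    x0, y0, x1, y1 = bbox
    cx, cy = int(round((x0 + x1) / 2)), int(round((y0 + y1) / 2))
    half = crop_size // 2
    r0, r1 = max(cy - half, 0), min(cy + half, h)
    c0, c1 = max(cx - half, 0), min(cx + half, w)
    if r0 >= r1 or c0 >= c1:
        return None
    diff = abs_difference(frame[r0:r1, c0:c1], reference[r0:r1, c0:c1], smooth_sigma)
    mask = diff > threshold
    if not mask.any():
        return None
    labeled = cc_label(mask, connectivity=2)
    center_label = labeled[min(cy - r0, r1 - r0 - 1), min(cx - c0, c1 - c0 - 1)]
    if center_label == 0:
        # nearest component to the crop center
        ys, xs = np.nonzero(labeled)
        d2 = (ys - (cy - r0)) ** 2 + (xs - (cx - c0)) ** 2
        center_label = labeled[ys[np.argmin(d2)], xs[np.argmin(d2)]]
    full = np.zeros((h, w), dtype=bool)
    full[r0:r1, c0:c1] = labeled == center_label
    return full


@dataclass(frozen=True)
class Morphometrics:
    area_um2: float
    h_um: float  # long side of the minimum-area enclosing rectangle
    w_um: float  # short side
    deformation_index: float
    equivalent_diameter_um: float


def min_area_rectangle(mask: np.ndarray) -> tuple[float, float]:
    """Side lengths (long, short) in px of the minimum-area rotated rectangle.

    Rotating calipers over the convex hull of the pixel *corners* (each mask
    pixel treated as a unit square), so an axis-aligned a x b pixel rectangle
    measures exactly (a, b).
    """
    coords = np.argwhere(mask)  # (row, col)
    if coords.size == 0:
        raise InputError("empty mask")
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    pts = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2).astype(float)
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError:  # degenerate (collinear) point sets
        hp = pts
    best = None
    n = len(hp)
    for i in range(n):
        edge = hp[(i + 1) % n] - hp[i]
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        u = edge / norm
        v = np.array([-u[1], u[0]])
        proj_u = hp @ u
        proj_v = hp @ v
        du = proj_u.max() - proj_u.min()
        dv = proj_v.max() - proj_v.min()
        if best is None or du * dv < best[0]:
            best = (du * dv, du, dv)
    if best is None:  # single point
        return (1.0, 1.0)
    _, du, dv = best
    return (max(du, dv), min(du, dv))


def morphometrics(mask: np.ndarray, pixel_size: float) -> Morphometrics:
    """Area, enclosing-rectangle sides (H >= W), deformation index, diameter."""
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise InputError("empty mask")
    area = n_px * pixel_size**2
    h_px, w_px = min_area_rectangle(mask)
    h_um, w_um = h_px * pixel_size, w_px * pixel_size
    di = (h_um - w_um) / (h_um + w_um)
    return Morphometrics(
        area_um2=area,
        h_um=h_um,
        w_um=w_um,
        deformation_index=di,
        equivalent_diameter_um=2.0 * math.sqrt(area / math.pi),
    )


def area_in_constriction(
    track: Track,
    masks_by_frame: dict[int, np.ndarray],
    geom: DeviceGeometry,
    constriction_id: int,
    require_fully_inside: bool = False,
) -> float | None:
    """Median segmented area (um^2) over frames with the cell in the constriction.

    Qualifying frames have the centroid strictly inside
    [entrance, entrance + length]; with ``require_fully_inside`` the whole
    bbox must lie inside (note deformed cells longer than the constriction
    then never qualify).  Returns None when no frame qualifies.
    """
    x_in = float(geom.entrance_x[constriction_id])
    x_out = x_in + geom.constriction_length_px
    areas = []
    for frame, bbox, (cx, _cy) in track.history:
        if frame not in masks_by_frame or masks_by_frame[frame] is None:
            continue
        if require_fully_inside:
            if not (bbox[0] >= x_in and bbox[2] <= x_out):
                continue
        elif not (x_in < cx < x_out):
            continue
        areas.append(masks_by_frame[frame].sum() * geom.pixel_size**2)
    if not areas:
        return None
    return float(np.median(areas))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def measure_cells(
    frames,
    tracks: list[Track],
    geom: DeviceGeometry,
    fps: float,
    regions: list[DetectionRegion] | None = None,
    windows: list[CreepWindow] | None = None,
    reference: np.ndarray | None = None,
    threshold: float | None = None,
    pre_entry_frames: int = 3,
    max_inside_frames: int = 15,
    crop_outside: int = 200,
    crop_inside: int = 50,
    require_fully_inside: bool = False,
    segmenter=None,
) -> pd.DataFrame:
    """Full measurement stage: one CellRecord row per confirmed track.

    A_cell is the median morphometric area over the ``pre_entry_frames``
    frames immediately before the entrance event; in-constriction quantities
    (area-in-constriction, H, W, deformation index) are medians over up to
    ``max_inside_frames`` evenly sampled qualifying frames.  Records missing
    an entrance or exit event are censored (passage time absent).

    ``segmenter(frame, bbox, crop_size) -> mask`` overrides the classical
    segmentation (e.g. a neural backend or a truth-mask oracle).
    """
    if reference is None:
        reference = background_reference(frames)
    if threshold is None:
        threshold = otsu_difference_threshold(frames, reference, smooth_sigma=1.0)
    if regions is None:
        regions = detection_regions(geom)
    if windows is None:
        windows = creep_window(geom)
    windows_by_cid = {w.constriction_id: w for w in windows}

    def _segment(frame_idx: int, bbox, crop_size: int):
        if segmenter is not None:
            return segmenter(frames[frame_idx], bbox, crop_size)
        return segment_crop(frames[frame_idx], reference, bbox, threshold, crop_size)

    events = region_events(tracks, regions, geom)
    ev_by_track: dict[tuple, RegionEvent] = {
        (e.track_id, e.kind): e for e in events
    }

    rows = []
    for t in tracks:
        cid = assign_constriction(t, geom)
        flags: list[str] = []
        ent = ev_by_track.get((t.track_id, "entrance"))
        exi = ev_by_track.get((t.track_id, "exit"))
        censored = ent is None or exi is None
        if censored:
            flags.append("missing_entrance" if ent is None else "missing_exit")
        p_time = np.nan
        if not censored:
            p_time = passage_time(ent, exi, fps)

        creep = creep_time(t, windows_by_cid[cid], fps)
        if creep.reason:
            flags.append(f"creep_{creep.reason}")

        history_by_frame = {h[0]: h for h in t.history}

        # undeformed cell area: median over frames just before the entrance event
        a_cell = np.nan
        eq_d = np.nan
        if ent is not None:
            pre_areas = []
            for f in range(ent.first_frame - pre_entry_frames, ent.first_frame):
                if f not in history_by_frame:
                    continue
                mask = _segment(f, history_by_frame[f][1], crop_outside)
                if mask is not None and mask.any():
                    pre_areas.append(mask.sum() * geom.pixel_size**2)
            if pre_areas:
                a_cell = float(np.median(pre_areas))
                eq_d = 2.0 * math.sqrt(a_cell / math.pi)
            else:
                flags.append("a_cell_segmentation_failed")

        # in-constriction frames: sampled evenly, segmented with the small crop
        x_in = float(geom.entrance_x[cid])
        x_out = x_in + geom.constriction_length_px
        inside = [h for h in t.history if x_in < h[2][0] < x_out]
        if len(inside) > max_inside_frames:
            sel = np.linspace(0, len(inside) - 1, max_inside_frames).astype(int)
            inside = [inside[i] for i in sel]
        crop_in = max(
            crop_inside, int(math.ceil(4 * a_cell / (math.pi * geom.constriction_width)
                                       / geom.pixel_size)) + 8 if np.isfinite(a_cell) else 0
        )
        masks_inside: dict[int, np.ndarray] = {}
        morphs = []
        for frame, bbox, _c in inside:
            mask = _segment(frame, bbox, crop_in)
            masks_inside[frame] = mask
            if mask is not None and mask.any():
                morphs.append(morphometrics(mask, geom.pixel_size))
        aic = area_in_constriction(
            t, masks_inside, geom, cid, require_fully_inside=require_fully_inside
        )
        if aic is None:
            flags.append("no_frame_in_constriction")
        h_um = float(np.median([m.h_um for m in morphs])) if morphs else np.nan
        w_um = float(np.median([m.w_um for m in morphs])) if morphs else np.nan
        di = (h_um - w_um) / (h_um + w_um) if morphs else np.nan

        rows.append(
            {
                "track_id": t.track_id,
                "constriction_id": cid,
                "group_label": geom.group_of(cid),
                "a_cell_um2": a_cell,
                "area_in_constriction_um2": np.nan if aic is None else aic,
                "h_um": h_um,
                "w_um": w_um,
                "deformation_index": di,
                "equivalent_diameter_um": eq_d,
                "passage_time_s": p_time,
                "t_creep_s": np.nan if creep.value is None else creep.value,
                "c1_per_cell": np.nan,  # filled by the rheology stage
                "censored": bool(censored),
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
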