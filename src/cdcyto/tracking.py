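"""Multi-object tracking: constant-velocity Kalman prediction + Hungarian
assignment on IoU.

A SORT-style tracker suited to constriction cytometry at ~1000 fps, where
inter-frame motion is a fraction of a cell diameter so bounding-box overlap
alone is a reliable association cue.  The motion state is
(cx, cy, w, h, vx, vy) with a linear constant-velocity filter; an optional
appearance term (patch intensity-histogram cosine similarity) can be blended
into the association cost with ``appearance_weight`` > 0.  Tracks are never
re-identified after loss: cells flow one way.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .autolabel import Detection
from .errors import ConfigurationError, SequencingError


@dataclass
class TrackerParams:
    iou_min: float = 0.3
    max_age: int = 5  # frames a confirmed track survives unmatched
    n_init: int = 2  # consecutive hits to confirm
    process_noise: float = 1e-2
    measurement_noise: float = 1e-1
    appearance_weight: float = 0.0  # 0 = IoU only

    def __post_init__(self):
        if not 0 < self.iou_min < 1:
            raise ConfigurationError("iou_min must be in (0, 1)")
        if self.max_age < 1:
            raise ConfigurationError("max_age must be >= 1")
        if not 0 <= self.appearance_weight <= 1:
            raise ConfigurationError("appearance_weight must be in [0, 1]")


def iou(box_a, box_b) -> float:
    """Intersection over union of half-open boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def iou_matrix(boxes_a, boxes_b) -> np.ndarray:
    m = np.zeros((len(boxes_a), len(boxes_b)))
    for i, a in enumerate(boxes_a):
        for j, b in enumerate(boxes_b):
            m[i, j] = iou(a, b)
    return m


class _KalmanBox:
    """Linear Kalman filter on state (cx, cy, w, h, vx, vy), dt = 1 frame."""

    _F = np.eye(6)
    _F[0, 4] = _F[1, 5] = 1.0
    _H = np.zeros((4, 6))
    _H[:4, :4] = np.eye(4)

    def __init__(self, z: np.ndarray, q: float, r: float):
        self.x = np.zeros(6)
        self.x[:4] = z
        self.P = np.diag([1.0, 1.0, 1.0, 1.0, 100.0, 100.0])  # uninformative velocity
        self.Q = q * np.diag([1.0, 1.0, 0.5, 0.5, 1.0, 1.0])
        self.R = r * np.eye(4)

    def predict(self) -> np.ndarray:
        self.x = self._F @ self.x
        self.P = self._F @ self.P @ self._F.T + self.Q
        return self.x[:4].copy()

    def peek(self) -> np.ndarray:
        """One-step-ahead state without committing it."""
        return (self._F @ self.x)[:4]

    def update(self, z: np.ndarray):
        y = z - self._H @ self.x
        s = self._H @ self.P @ self._H.T + self.R
        k = self.P @ self._H.T @ np.linalg.inv(s)
        self.x = self.x + k @ y
        self.P = (np.eye(6) - k @ self._H) @ self.P


def _bbox_to_z(bbox) -> np.ndarray:
    x0, y0, x1, y1 = bbox
    return np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0, x1 - x0, y1 - y0])


def _z_to_bbox(z) -> tuple:
    cx, cy, w, h = z
    return (cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)


@dataclass
class Track:
    """Identity-resolved trajectory of one cell.

    ``history`` holds (frame_index, bbox, centroid) in strictly increasing
    frame order; track ids are never reused within a run.
    """

    track_id: int
    history: list = field(default_factory=list)  # (frame, bbox, (cx, cy))
    state: str = "tentative"  # tentative | confirmed | lost
    misses: int = 0
    hits: int = 1
    ever_confirmed: bool = False
    kf: _KalmanBox | None = None

    @property
    def last_frame(self) -> int:
        return self.history[-1][0]

    @property
    def last_bbox(self) -> tuple:
        return self.history[-1][1]

    def frames(self) -> np.ndarray:
        return np.array([h[0] for h in self.history])

    def centroids(self) -> np.ndarray:
        return np.array([h[2] for h in self.history], dtype=float)


def predict(tracks: list[Track]) -> list[tuple]:
    """Constant-velocity bbox prediction for each track (non-mutating).

    A track with a single observation has zero estimated velocity, so its
    prediction equals its last box (the filter's velocity prior is centred
    on zero).
    """
    out = []
    for t in tracks:
        if t.kf is None:
            out.append(t.last_bbox)
        else:
            out.append(_z_to_bbox(t.kf.peek()))
    return out


def associate(predictions, detections, iou_min: float = 0.3):
    """Hungarian assignment maximizing total IoU.

    Returns (matches, unmatched_track_idx, unmatched_detection_idx); matched
    pairs with IoU < ``iou_min`` are demoted to unmatched.  Ties resolve to
    the lowest (track index, detection index) pair through the solver's
    row-major scan order.
    """
    det_boxes = [d.bbox if isinstance(d, Detection) else d for d in detections]
    n_t, n_d = len(predictions), len(det_boxes)
    if n_t == 0 or n_d == 0:
        return [], list(range(n_t)), list(range(n_d))
    m = iou_matrix(predictions, det_boxes)
    rows, cols = linear_sum_assignment(-m)
    matches = []
    matched_t, matched_d = set(), set()
    for r, c in zip(rows, cols):
        if m[r, c] >= iou_min and m[r, c] > 0:
            matches.append((int(r), int(c)))
            matched_t.add(int(r))
            matched_d.add(int(c))
    unmatched_t = [i for i in range(n_t) if i not in matched_t]
    unmatched_d = [j for j in range(n_d) if j not in matched_d]
    return matches, unmatched_t, unmatched_d


def brute_force_assignment(m: np.ndarray) -> float:
    """Maximum total score over all one-to-one assignments (test oracle).

    Exhaustive over permutations; intended for matrices with <= ~6 columns.
    """
    n_t, n_d = m.shape
    best = 0.0
    if n_t <= n_d:
        for cols in itertools.permutations(range(n_d), n_t):
            best = max(best, sum(m[r, c] for r, c in enumerate(cols)))
    else:
        for rows in itertools.permutations(range(n_t), n_d):
            best = max(best, sum(m[r, c] for c, r in enumerate(rows)))
    return best


class Tracker:
    """Stateful frame-by-frame tracker (see module docstring).

    Lifecycle: a new detection spawns a tentative track; ``n_init``
    consecutive hits confirm it; a tentative track is dropped on its first
    miss; a confirmed track unmatched for more than ``max_age`` frames
    becomes lost and is frozen (no re-identification).
    """

    def __init__(self, params: TrackerParams | None = None):
        self.params = params or TrackerParams()
        self.tracks: list[Track] = []
        self._next_id = 0
        self._last_frame = -1

    @property
    def active_tracks(self) -> list[Track]:
        return [t for t in self.tracks if t.state != "lost"]

    def step(self, detections: list[Detection], frame_index: int | None = None) -> list[Track]:
        """Advance one frame: associate, update, spawn, age."""
        if frame_index is None:
            frame_index = detections[0].frame_index if detections else self._last_frame + 1
        if frame_index <= self._last_frame:
            raise SequencingError(
                f"frame {frame_index} is not after last processed frame {self._last_frame}"
            )
        for d in detections:
            if d.frame_index != frame_index:
                raise SequencingError(
                    f"detection frame {d.frame_index} != step frame {frame_index}"
                )
        self._last_frame = frame_index

        active = self.active_tracks
        preds = []
        for t in active:  # commit the one-step prediction so misses coast
            preds.append(t.last_bbox if t.kf is None else _z_to_bbox(t.kf.predict()))
        matches, unmatched_t, unmatched_d = associate(
            preds, detections, self.params.iou_min
        )
        for ti, di in matches:
            t, d = active[ti], detections[di]
            if t.kf is None:
                t.kf = _KalmanBox(
                    _bbox_to_z(t.last_bbox),
                    self.params.process_noise,
                    self.params.measurement_noise,
                )
                t.kf.predict()
            t.kf.update(_bbox_to_z(d.bbox))
            t.history.append((frame_index, d.bbox, d.center))
            t.misses = 0
            t.hits += 1
            if t.state == "tentative" and t.hits >= self.params.n_init:
                t.state = "confirmed"
                t.ever_confirmed = True
        for ti in unmatched_t:
            t = active[ti]
            t.misses += 1
            t.hits = 0
            if t.state == "tentative" or t.misses > self.params.max_age:
                t.state = "lost"
        for di in unmatched_d:
            d = detections[di]
            self.tracks.append(
                Track(
                    track_id=self._next_id,
                    history=[(frame_index, d.bbox, d.center)],
                )
            )
            self._next_id += 1
        return self.tracks

    def finalize(self) -> list[Track]:
        """Tracks that were confirmed at some point, in id order."""
        return [t for t in self.tracks if t.ever_confirmed]


def track_detections(
    detections_by_frame: list[list[Detection]], params: TrackerParams | None = None
) -> list[Track]:
    """Track a whole video's detections; returns confirmed tracks."""
    tracker = Tracker(params)
    for f, dets in enumerate(detections_by_frame):
        tracker.step(dets, frame_index=f)
    return tracker.finalize()


def tracks_to_frame(tracks: list[Track], run_id: str = "run0"):
    """Serialize tracks to the documented CSV layout."""
    import pandas as pd

    rows: list[dict] = []
    for t in tracks:
        for frame, bbox, (cx, cy) in t.history:
            x0, y0, x1, y1 = bbox
            rows.append(
                {
                    "run_id": run_id,
                    "track_id": t.track_id,
                    "frame_index": frame,
                    "x_min": x0,
                    "y_min": y0,
                    "x_max": x1,
                    "y_max": y1,
                    "cx": cx,
                    "cy": cy,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["run_id", "track_id", "frame_index", "x_min", "y_min", "x_max", "y_max", "cx", "cy"],
    )
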