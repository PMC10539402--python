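"""Automatic training-set generation and classical cell detection.

Moving cells are found from the difference between each frame and a
background reference: absolute difference -> threshold -> dilation ->
connected components -> bounding boxes.  The resulting boxes serve two
purposes: (i) exported as normalized center-box annotation text files they
bootstrap a neural detector's training set without manual labeling, and
(ii) they double as the runtime detector of the pipeline (score 1.0), so
the full pipeline is testable without trained weights.  A neural detector
can be plugged in anywhere a ``list[Detection]`` per frame is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk

from .errors import InputError


@dataclass(frozen=True)
class Detection:
    """One detected object in one frame.

    ``bbox`` is (x_min, y_min, x_max, y_max) in px, half-open; ``centroid``
    is the (cx, cy) center of mass of the component (sub-pixel), which is
    more stable than the bbox center under noise.
    """

    frame_index: int
    bbox: tuple
    score: float = 1.0
    centroid: tuple | None = None

    @property
    def center(self) -> tuple:
        if self.centroid is not None:
            return self.centroid
        x0, y0, x1, y1 = self.bbox
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def background_reference(
    frames: Sequence[np.ndarray] | np.ndarray,
    method: str = "median",
    n_sample: int = 200,
) -> np.ndarray:
    """Estimate a cell-free background frame.

    ``median`` (default) takes the per-pixel median over at most ``n_sample``
    uniformly sampled frames — robust as long as each pixel shows background
    in more than half the sampled frames.  ``first`` returns frame 0;
    ``mean`` is the per-pixel average of the sample.
    """
    n = len(frames)
    if n == 0:
        raise InputError("cannot build a background reference from an empty sequence")
    if method == "first":
        return np.asarray(frames[0]).copy()
    idx = np.unique(np.linspace(0, n - 1, min(n_sample, n)).astype(int))
    stack = np.stack([np.asarray(frames[i]) for i in idx])
    if method == "median":
        return np.median(stack, axis=0).astype(stack.dtype)
    if method == "mean":
        return stack.mean(axis=0).astype(stack.dtype)
    raise InputError(f"unknown background method {method!r}")


def abs_difference(
    frame: np.ndarray, reference: np.ndarray, smooth_sigma: float = 0.0
) -> np.ndarray:
    """|frame - reference| with signed-safe arithmetic for unsigned dtypes.

    ``smooth_sigma`` > 0 low-pass filters the *signed* difference first:
    noise at the blurred cell boundary otherwise shatters the thresholded
    contour into shards.  The smoothing is symmetric, so the half-contrast
    boundary (and hence the measured area) stays unbiased.
    """
    frame = np.asarray(frame)
    reference = np.asarray(reference)
    if frame.shape != reference.shape:
        raise InputError(
            f"frame shape {frame.shape} does not match reference {reference.shape}"
        )
    diff = frame.astype(np.float64) - reference.astype(np.float64)
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        diff = gaussian_filter(diff, smooth_sigma)
    return np.abs(diff)


def otsu_difference_threshold(
    frames: Sequence[np.ndarray],
    reference: np.ndarray,
    n_sample: int = 50,
    smooth_sigma: float = 0.0,
) -> float:
    """Global Otsu threshold on the pooled absolute-difference histogram.

    Pooling over a frame sample (which contains cells) keeps the threshold
    meaningful on frames that happen to be empty, where a per-frame Otsu
    would split the noise distribution itself.
    """
    n = len(frames)
    if n == 0:
        raise InputError("empty frame sequence")
    idx = np.unique(np.linspace(0, n - 1, min(n_sample, n)).astype(int))
    diffs = np.concatenate(
        [abs_difference(frames[i], reference, smooth_sigma).ravel() for i in idx]
    )
    if diffs.max() == diffs.min():
        return float(diffs.max())  # constant video: nothing is foreground
    return float(threshold_otsu(diffs))


def foreground_mask(frame: np.ndarray, reference: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask of pixels where |frame - reference| > threshold."""
    return abs_difference(frame, reference) > threshold


def dilate_mask(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Dilate with a disk structuring element; radius 0 is the identity."""
    if radius_px < 0:
        raise InputError("radius_px must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius_px == 0:
        return mask.copy()
    return binary_dilation(mask, structure=disk(radius_px))


def mask_to_detections(
    mask: np.ndarray, min_area_px: int = 50, frame_index: int = 0
) -> list[Detection]:
    """One Detection per 8-connected component with area >= ``min_area_px``.

    Classical detections carry score 1.0; output is ordered by (y_min, x_min).
    """
    labeled = cc_label(np.asarray(mask, dtype=bool), connectivity=2)
    dets = []
    for prop in regionprops(labeled):
        if prop.area < min_area_px:
            continue
        y0, x0, y1, x1 = prop.bbox  # skimage bbox is half-open
        cy, cx = prop.centroid
        dets.append(
            Detection(
                frame_index=frame_index,
                bbox=(int(x0), int(y0), int(x1), int(y1)),
                score=1.0,
                centroid=(float(cx), float(cy)),
            )
        )
    dets.sort(key=lambda d: (d.bbox[1], d.bbox[0]))
    return dets


def detect_frames(
    frames,
    reference: np.ndarray | None = None,
    threshold: float | None = None,
    dilate_radius: int = 2,
    min_area_px: int = 50,
    background_method: str = "median",
    smooth_sigma: float = 1.0,
) -> list[list[Detection]]:
    """Run the classical detector over a whole sequence.

    Builds the background reference and the global Otsu threshold from the
    sequence itself unless supplied.  Returns one detection list per frame.
    """
    if len(frames) == 0:
        raise InputError("empty frame sequence")
    if reference is None:
        reference = background_reference(frames, method=background_method)
    if threshold is None:
        threshold = otsu_difference_threshold(frames, reference, smooth_sigma=smooth_sigma)
    out = []
    for i in range(len(frames)):
        mask = abs_difference(frames[i], reference, smooth_sigma) > threshold
        mask = dilate_mask(mask, dilate_radius)
        out.append(mask_to_detections(mask, min_area_px=min_area_px, frame_index=i))
    return out


# ---------------------------------------------------------------------------
# annotation export: one text file per frame, lines
#   "<class> <x_center> <y_center> <width> <height>"  normalized to [0, 1]
# (the single-stage-detector text dialect)
# ---------------------------------------------------------------------------

def export_annotations(
    detections_by_frame: Iterable[list[Detection]],
    image_shape: tuple,
    out_dir: str | Path,
    class_id: int = 0,
    prefix: str = "frame",
) -> list[Path]:
    """Write normalized center-box annotation files, one per frame.

    Frames with no detections get an empty file (the dialect's convention for
    a negative image).  Round-trips through :func:`read_annotations` are
    lossless up to 6-decimal coordinate quantization.
    """
    h, w = image_shape[:2]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, dets in enumerate(detections_by_frame):
        lines = []
        for d in dets:
            x0, y0, x1, y1 = d.bbox
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise InputError(f"bbox {d.bbox} outside image bounds {(w, h)}")
            xc, yc = (x0 + x1) / 2.0 / w, (y0 + y1) / 2.0 / h
            bw, bh = (x1 - x0) / w, (y1 - y0) / h
            lines.append(f"{class_id} {xc:.6f} {yc:.6f} {bw:.6f} {bh:.6f}")
        p = out_dir / f"{prefix}_{i:06d}.txt"
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths.append(p)
    return paths


def read_annotations(path: str | Path, image_shape: tuple) -> list[Detection]:
    """Read one annotation file back to pixel-space detections."""
    h, w = image_shape[:2]
    dets = []
    text = Path(path).read_text().strip()
    if not text:
        return dets
    for line in text.splitlines():
        parts = line.split()
        if len(parts) != 5:
            raise InputError(f"malformed annotation line: {line!r}")
        _, xc, yc, bw, bh = (float(v) for v in parts)
        x0, x1 = (xc - bw / 2) * w, (xc + bw / 2) * w
        y0, y1 = (yc - bh / 2) * h, (yc + bh / 2) * h
        dets.append(Detection(frame_index=-1, bbox=(x0, y0, x1, y1)))
    return dets
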