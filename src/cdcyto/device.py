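"""Microfluidic chip geometry: constriction layout, detection regions, creep windows.

The device is a parallel-microconstriction chip: ``n_groups`` groups of
``constrictions_per_group`` constrictions, each constriction a rectangular
channel (default 10 x 30 x 60 um, width x height x length) fed by a 25 um
lead channel.  All downstream modules share one coordinate convention:

* pixels, origin top-left, x increases along the flow direction,
* 0-based frame and pixel indexing,
* physical units (um) obtained through ``pixel_size`` (um/px).

Conversions px <-> um are kept in floating point everywhere; rounding
(half away from zero) happens only at a final conversion when an integer
pixel value is explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError

#: default creep-window half-length (um): mean of the measured mean diameters
#: of the two reference breast-cancer lines (12.75 and 13.15 um).
DEFAULT_CREEP_HALF_LENGTH_UM = 12.95


def round_half_away(x):
    """Round half away from zero (scalar or array).

    Used only at final px<->um conversions so rounding error never accumulates.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class DeviceGeometry:
    """Chip layout plus pixel calibration.

    ``entrance_x`` / ``lane_y`` hold one value per constriction (px).  The
    entrance plane is the upstream face of the constriction throat; the
    constriction occupies ``[entrance_x, entrance_x + length/pixel_size]``.
    """

    n_groups: int = 4
    constrictions_per_group: int = 9
    constriction_width: float = 10.0  # um
    constriction_height: float = 30.0  # um
    constriction_length: float = 60.0  # um
    lead_channel_width: float = 25.0  # um
    pixel_size: float = 0.65  # um/px
    entrance_x: np.ndarray = field(default=None)  # px, per constriction
    lane_y: np.ndarray = field(default=None)  # px, per constriction
    lane_pitch: float = 50.0  # um, transverse spacing of lanes
    group_gap: float = 30.0  # um, extra gap between groups

    @property
    def n_constrictions(self) -> int:
        return self.n_groups * self.constrictions_per_group

    @property
    def constriction_length_px(self) -> float:
        return self.constriction_length / self.pixel_size

    @property
    def constriction_width_px(self) -> float:
        return self.constriction_width / self.pixel_size

    def end_x(self) -> np.ndarray:
        """Downstream end of each constriction (px)."""
        return np.asarray(self.entrance_x, dtype=float) + self.constriction_length_px

    def group_of(self, constriction_id: int) -> int:
        return int(constriction_id) // self.constrictions_per_group

    def um_to_px(self, um):
        return np.asarray(um, dtype=float) / self.pixel_size

    def px_to_um(self, px):
        return np.asarray(px, dtype=float) * self.pixel_size

    def nearest_constriction(self, y_px: float) -> int:
        """Lane assignment: index of the constriction whose lane_y is closest."""
        return int(np.argmin(np.abs(np.asarray(self.lane_y, dtype=float) - y_px)))


@dataclass(frozen=True)
class DetectionRegion:
    """Axis-aligned focal region used for passage-time event logging.

    ``kind`` is ``"entrance"`` (upstream of the entrance plane) or ``"exit"``
    (downstream of the constriction end).  Membership is tested on the cell
    centroid; boxes are half-open conceptually but stored as center+half-size.
    """

    constriction_id: int
    kind: str  # "entrance" | "exit"
    center: tuple  # (x, y) px
    half_size: tuple  # (hx, hy) px

    def contains(self, x: float, y: float) -> bool:
        cx, cy = self.center
        hx, hy = self.half_size
        return (cx - hx <= x < cx + hx) and (cy - hy <= y < cy + hy)


@dataclass(frozen=True)
class CreepWindow:
    """Window of +/- ``half_length`` um centered on the entrance plane.

    A cell's creep time is the time its centroid takes to traverse
    ``[x_start, x_end]``.
    """

    constriction_id: int
    x_start: float  # px
    x_end: float  # px
    half_length: float  # um


_DIMENSIONAL_FIELDS = (
    "constriction_width",
    "constriction_height",
    "constriction_length",
    "lead_channel_width",
    "pixel_size",
    "lane_pitch",
)


def build_geometry(config: Mapping | None = None) -> DeviceGeometry:
    """Build a fully-populated :class:`DeviceGeometry` from a key-value map.

    Unspecified fields take the chip defaults (4 groups x 9 constrictions of
    10 x 30 x 60 um).  If ``entrance_x``/``lane_y`` are not given, lanes are
    laid out top-to-bottom at ``lane_pitch`` spacing (plus ``group_gap``
    between groups) with a common entrance plane at ``entrance_x_um``
    (default 60 um) downstream of the left frame edge.

    Raises
    ------
    ConfigurationError
        if any dimensional value is non-positive or counts are < 1.
    """
    config = dict(config or {})
    entrance_x_um = float(config.pop("entrance_x_um", 60.0))
    kwargs = {}
    for f in (
        "n_groups",
        "constrictions_per_group",
        *_DIMENSIONAL_FIELDS,
        "group_gap",
        "entrance_x",
        "lane_y",
    ):
        if f in config:
            kwargs[f] = config.pop(f)
    if config:
        raise ConfigurationError(f"unknown geometry fields: {sorted(config)}")

    geom = DeviceGeometry(**kwargs)
    geom.n_groups = int(geom.n_groups)
    geom.constrictions_per_group = int(geom.constrictions_per_group)
    if geom.n_groups < 1 or geom.constrictions_per_group < 1:
        raise ConfigurationError("n_groups and constrictions_per_group must be >= 1")
    for f in _DIMENSIONAL_FIELDS:
        v = float(getattr(geom, f))
        if not v > 0:
            raise ConfigurationError(f"geometry field {f!r} must be > 0, got {v}")
        setattr(geom, f, v)
    if geom.group_gap < 0:
        raise ConfigurationError("group_gap must be >= 0")
    if not geom.constriction_width < geom.lead_channel_width:
        raise ConfigurationError(
            "constriction_width must be narrower than lead_channel_width "
            f"({geom.constriction_width} >= {geom.lead_channel_width})"
        )

    n = geom.n_constrictions
    if geom.entrance_x is None:
        geom.entrance_x = np.full(n, entrance_x_um / geom.pixel_size)
    else:
        geom.entrance_x = np.asarray(geom.entrance_x, dtype=float)
    if geom.lane_y is None:
        ys = []
        for cid in range(n):
            g = cid // geom.constrictions_per_group
            lane = cid % geom.constrictions_per_group
            y_um = (
                geom.lane_pitch / 2.0
                + (g * geom.constrictions_per_group + lane) * geom.lane_pitch
                + g * geom.group_gap
            )
            ys.append(y_um / geom.pixel_size)
        geom.lane_y = np.asarray(ys)
    else:
        geom.lane_y = np.asarray(geom.lane_y, dtype=float)

    if len(geom.entrance_x) != n or len(geom.lane_y) != n:
        raise ConfigurationError(
            f"entrance_x/lane_y must have one entry per constriction (n={n})"
        )
    return geom


def detection_regions(
    geom: DeviceGeometry,
    offsets: Sequence[float] = (18.0, 10.0),
    half_width: float = 4.0,
    half_height: float | None = None,
) -> list[DetectionRegion]:
    """Entrance/exit focal regions for every constriction.

    Parameters
    ----------
    offsets : (um, um)
        Upstream offset of the entrance-region center from the entrance plane
        and downstream offset of the exit-region center from the constriction
        end.  ``(0, 0)`` centers the regions exactly on those planes.
    half_width : um
        Half-extent of each region along the flow (x) axis.
    half_height : um, optional
        Half-extent transverse to flow; defaults to half the lead channel.

    Returns exactly two regions per constriction, ordered by
    (group, lane, kind) with "entrance" before "exit".
    """
    off_in, off_out = (float(offsets[0]), float(offsets[1]))
    if half_height is None:
        half_height = geom.lead_channel_width / 2.0
    if half_width <= 0 or half_height <= 0:
        raise ConfigurationError("region half extents must be > 0")

    hx = half_width / geom.pixel_size
    hy = half_height / geom.pixel_size
    regions: list[DetectionRegion] = []
    end_x = geom.end_x()
    for cid in range(geom.n_constrictions):
        ent_cx = float(geom.entrance_x[cid]) - off_in / geom.pixel_size
        exit_cx = float(end_x[cid]) + off_out / geom.pixel_size
        if ent_cx >= exit_cx:
            raise ConfigurationError(
                f"offsets {offsets} invert region order for constriction {cid}: "
                f"entrance center {ent_cx:.1f} px >= exit center {exit_cx:.1f} px"
            )
        y = float(geom.lane_y[cid])
        regions.append(DetectionRegion(cid, "entrance", (ent_cx, y), (hx, hy)))
        regions.append(DetectionRegion(cid, "exit", (exit_cx, y), (hx, hy)))
    return regions


def creep_window(
    geom: DeviceGeometry, half_length: float = DEFAULT_CREEP_HALF_LENGTH_UM
) -> list[CreepWindow]:
    """Per-constriction creep window spanning entrance +/- ``half_length`` um."""
    if not half_length > 0:
        raise ConfigurationError(f"half_length must be > 0, got {half_length}")
    hl_px = half_length / geom.pixel_size
    return [
        CreepWindow(cid, float(geom.entrance_x[cid]) - hl_px,
                    float(geom.entrance_x[cid]) + hl_px, half_length)
        for cid in range(geom.n_constrictions)
    ]
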