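"""Ground-truthed synthetic constriction-cytometry videos.

Generates grayscale time-lapse sequences of cells approaching, creeping into,
and transiting parallel microconstrictions, with kinematics that obey the
power-law creep model of :mod:`cdcyto.rheology`:

* each cell carries an area A, stiffness index c1 and exponent beta; its
  creep time is the forward model t_creep = c1 * (1 - c2/sqrt(A))**(1/beta);
* within the creep window the position fraction follows s(t) = (t/t_creep)**beta,
  a decelerating power-law displacement that traverses the window in exactly
  t_creep; approach and transit are constant-speed;
* outside the constriction cells are disks of the specified area; inside, they
  are ellipses whose transverse axis is clamped to the constriction width and
  whose longitudinal axis preserves projected area (2-D incompressibility,
  H = 4A / (pi * W_c)).  The renderer morphs smoothly between the two shapes
  across the creep window (and back on exit) so that the projected outline
  deforms gradually, as a real cell does.

Every video comes with a :class:`SyntheticTruth`: the per-cell parameter
table (including exact t_creep and event frames) and the per-frame rendered
object table, so detection, tracking and measurement can be scored exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .device import CreepWindow, DeviceGeometry, build_geometry, creep_window
from .errors import ConfigurationError, InputError
from .rheology import DEFAULT_C2_UM, forward_creep_time

#: optimal cell-size support (um^2) for the default 10 um constriction; the
#: simulator draws areas from this range so every cell deforms (A > c2^2).
DEFAULT_AREA_RANGE = (547.1357, 1034.096)


@dataclass
class PopulationSpec:
    """One cell population in a mixture.

    c1 is log-normal: ``c1_median`` sets the median (in t0 = 1 s units) and
    ``c1_gsd`` the geometric standard deviation.  Areas are uniform (or
    truncated-normal) on ``area_range``; the support must satisfy
    A > c2^2 so that eps_e > 0 for every sampled cell.
    """

    name: str
    fraction: float
    c1_median: float
    c1_gsd: float = 1.25
    beta: float = 0.5
    area_range: tuple = DEFAULT_AREA_RANGE
    area_dist: str = "uniform"  # "uniform" | "truncnorm"

    def __post_init__(self):
        if not 0 <= self.fraction <= 1:
            raise ConfigurationError("population fraction must be in [0, 1]")
        if not self.c1_median > 0 or not self.c1_gsd >= 1:
            raise ConfigurationError("c1_median must be > 0 and c1_gsd >= 1")
        if not 0 < self.beta <= 1:
            raise ConfigurationError("beta must be in (0, 1]")
        if not self.area_range[0] < self.area_range[1]:
            raise ConfigurationError("area_range must be increasing")


def default_population_specs(
    stiff_fraction: float = 0.5,
    c1_stiff: float = 0.48,
    c1_soft: float = 0.12,
) -> list[PopulationSpec]:
    """Two-population benchmark: a stiff and a soft line at a ~4x c1 ratio.

    The ratio mirrors the reference breast-cancer pair (stiff epithelial-like
    vs soft mesenchymal-like); absolute medians are chosen so creep events
    span tens of frames at 988 fps.
    """
    return [
        PopulationSpec("stiff", stiff_fraction, c1_stiff),
        PopulationSpec("soft", 1.0 - stiff_fraction, c1_soft),
    ]


@dataclass
class ImagingModel:
    """Camera / optics model for rendering (8-bit grayscale)."""

    fps: float = 988.0
    background: float = 180.0
    cell_contrast: float = -60.0
    blur_sigma: float = 1.0
    noise_sigma: float = 2.0

    def __post_init__(self):
        if not self.fps > 0:
            raise ConfigurationError("fps must be > 0")
        if not (0 <= self.background <= 255 and 0 <= self.background + self.cell_contrast <= 255):
            raise ConfigurationError("background and cell intensity must fit 8-bit range")


@dataclass
class SimCell:
    """One synthetic cell: identity, mechanics, and (after scheduling) timing."""

    cell_id: int
    population: str
    area_um2: float
    c1: float
    beta: float
    t_creep: float
    constriction_id: int = -1
    launch_frame: int = -1
    stall: bool = False  # occluder: stops inside the constriction and stays


def sample_population(
    specs: list[PopulationSpec],
    n_cells: int,
    seed=None,
    c2: float = DEFAULT_C2_UM,
    exact_fractions: bool = False,
) -> list[SimCell]:
    """Draw a reproducible mixture of synthetic cells.

    Population counts are multinomial in ``fractions`` unless
    ``exact_fractions`` is set, in which case counts are
    round(n * fraction) corrected to sum to n (largest fraction absorbs the
    remainder), as when pipetting a fixed-ratio mixture.
    """
    if n_cells < 0:
        raise InputError("n_cells must be >= 0")
    fracs = np.array([s.fraction for s in specs], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"population fractions must sum to 1, got {fracs.sum()}")
    for s in specs:
        if s.area_range[0] <= c2**2:
            raise ConfigurationError(
                f"population {s.name!r}: area support must exceed c2^2 = "
                f"{c2 ** 2:.4f} um^2, got min {s.area_range[0]}"
            )
    rng = np.random.default_rng(seed)
    if n_cells == 0:
        return []
    if exact_fractions:
        counts = np.floor(fracs * n_cells).astype(int)
        # distribute the remainder by largest fractional part, ties to lower index
        rem = n_cells - counts.sum()
        order = np.argsort(-(fracs * n_cells - counts), kind="stable")
        counts[order[:rem]] += 1
    else:
        counts = rng.multinomial(n_cells, fracs)

    cells: list[SimCell] = []
    cid = 0
    for spec, k in zip(specs, counts):
        lo, hi = spec.area_range
        if spec.area_dist == "uniform":
            areas = rng.uniform(lo, hi, size=k)
        elif spec.area_dist == "truncnorm":
            mu, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
            areas = np.clip(rng.normal(mu, sd, size=k), lo, hi)
        else:
            raise ConfigurationError(f"unknown area_dist {spec.area_dist!r}")
        c1s = spec.c1_median * np.exp(rng.normal(0.0, math.log(spec.c1_gsd), size=k))
        for a, c1 in zip(areas, c1s):
            cells.append(
                SimCell(
                    cell_id=cid,
                    population=spec.name,
                    area_um2=float(a),
                    c1=float(c1),
                    beta=spec.beta,
                    t_creep=forward_creep_time(float(a), float(c1), spec.beta, c2),
                )
            )
            cid += 1
    return cells


def cells_to_frame(cells: list[SimCell]) -> pd.DataFrame:
    """Tabulate a list of :class:`SimCell` as a DataFrame."""
    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "population": c.population,
                "area_um2": c.area_um2,
                "c1": c.c1,
                "beta": c.beta,
                "t_creep": c.t_creep,
                "constriction_id": c.constriction_id,
                "launch_frame": c.launch_frame,
                "stall": c.stall,
            }
            for c in cells
        ]
    )


@dataclass
class KinematicsParams:
    """Speeds and margins of the piecewise trajectory (um, um/s, frames)."""

    approach_speed: float = 600.0
    transit_speed: float = 1000.0
    approach_margin: float = 25.0  # launch distance upstream of the creep window
    exit_margin: float = 19.0  # distance past the exit-region outer edge to keep drawing
    # per-lane gap between one cell finishing and the next launch; large enough
    # that any pixel sees background in > 50% of frames, keeping the per-pixel
    # median reference uncontaminated by slowly creeping cells
    headway_frames: int = 150

    def __post_init__(self):
        if self.approach_speed <= 0 or self.transit_speed <= 0:
            raise ConfigurationError("speeds must be > 0")


class CellPath:
    """Continuous-time trajectory and shape of one cell along its lane.

    Piecewise in um (converted to px on demand):

    * approach: constant ``approach_speed`` from the launch point to the
      creep-window start;
    * creep: window fraction s(t) = (t/t_creep)**beta — the window is
      traversed in exactly ``t_creep``;
    * transit: constant ``transit_speed`` from the window end until the cell
      leaves the field of interest (or stalls, for occluders).

    The trajectory is continuous at stage boundaries.
    """

    def __init__(
        self,
        cell: SimCell,
        geom: DeviceGeometry,
        window: CreepWindow,
        kin: KinematicsParams,
        fps: float,
    ):
        self.cell = cell
        self.geom = geom
        self.kin = kin
        self.fps = fps
        ps = geom.pixel_size
        self.w0 = window.x_start * ps  # um
        self.w1 = window.x_end * ps
        self.entrance = float(geom.entrance_x[cell.constriction_id]) * ps
        self.end = self.entrance + geom.constriction_length
        self.radius = math.sqrt(cell.area_um2 / math.pi)
        self.x0 = self.w0 - kin.approach_margin
        self.t1 = kin.approach_margin / kin.approach_speed  # creep start
        self.t2 = self.t1 + cell.t_creep  # creep end
        exit_outer = self.end + kin.exit_margin
        self.x_stop = (self.entrance + geom.constriction_length / 3.0) if cell.stall else exit_outer
        self.t3 = self.t2 + max(self.x_stop - self.w1, 0.0) / kin.transit_speed
        self.recovery_length = 2.0 * self.radius

    # -- kinematics ---------------------------------------------------------
    def x_um(self, t):
        """Position (um) at time t (s) since launch; clamped at x_stop."""
        t = np.asarray(t, dtype=float)
        c = self.cell
        x = np.empty(t.shape)
        approach = t < self.t1
        creep = (t >= self.t1) & (t < self.t2)
        after = t >= self.t2
        x[approach] = self.x0 + self.kin.approach_speed * t[approach]
        s = ((t[creep] - self.t1) / c.t_creep) ** c.beta
        x[creep] = self.w0 + s * (self.w1 - self.w0)
        x[after] = self.w1 + self.kin.transit_speed * (t[after] - self.t2)
        x = np.minimum(x, self.x_stop)
        return float(x) if x.ndim == 0 else x

    def t_at_x(self, x_um: float) -> float:
        """First time (s since launch) the centroid reaches position x (um)."""
        if x_um <= self.x0:
            return 0.0
        if x_um <= self.w0:
            return (x_um - self.x0) / self.kin.approach_speed
        if x_um <= self.w1:
            s = (x_um - self.w0) / (self.w1 - self.w0)
            return self.t1 + self.cell.t_creep * s ** (1.0 / self.cell.beta)
        if x_um >= self.x_stop and self.cell.stall:
            return math.inf
        return self.t2 + (min(x_um, self.x_stop) - self.w1) / self.kin.transit_speed

    def first_frame_at(self, x_um: float) -> int:
        """First absolute frame index whose sampled position is >= x (um)."""
        t = self.t_at_x(x_um)
        if math.isinf(t):
            return -1
        return self.cell.launch_frame + int(math.ceil(t * self.fps - 1e-9))

    @property
    def last_frame(self) -> int:
        """Last frame on which the cell is drawn (inf for stalled occluders)."""
        if self.cell.stall:
            return -1
        return self.cell.launch_frame + int(math.ceil(self.t3 * self.fps + 1e-9))

    # -- shape --------------------------------------------------------------
    def shape_um(self, x_um: float) -> tuple[float, float]:
        """(semi-axis along flow, semi-axis transverse) in um at position x.

        Disk upstream of the creep window; linear width morph from 2R down to
        the constriction width across the window; fully clamped ellipse inside
        the constriction; reverse morph over ``recovery_length`` past the end.
        Area is preserved throughout (2-D incompressibility).
        """
        a_cell = self.cell.area_um2
        r = self.radius
        wc = self.geom.constriction_width
        if x_um < self.w0:
            width = 2.0 * r
        elif x_um <= self.w1:
            s = (x_um - self.w0) / (self.w1 - self.w0)
            width = 2.0 * r + s * (wc - 2.0 * r)
        elif x_um <= self.end:
            width = wc
        else:
            s = min((x_um - self.end) / self.recovery_length, 1.0)
            width = wc + s * (2.0 * r - wc)
        semi_transverse = width / 2.0
        semi_flow = a_cell / (math.pi * semi_transverse)
        return semi_flow, semi_transverse


def cell_kinematics(
    cell: SimCell,
    geom: DeviceGeometry,
    window: CreepWindow,
    kin: KinematicsParams | None = None,
    fps: float = 988.0,
) -> CellPath:
    """Build the piecewise trajectory of ``cell`` through ``window``."""
    if cell.t_creep <= 0:
        raise InputError("cell.t_creep must be computed and > 0")
    return CellPath(cell, geom, window, kin or KinematicsParams(), fps)


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every rendered video.

    cells : DataFrame
        one row per cell — parameters, lane, launch/entry/exit frames and the
        exact forward-model t_creep.  ``entry_frame``/``creep_end_frame`` are
        the first frames with centroid past the window start/end;
        ``exit_frame`` is the first frame past the constriction end.
    objects : DataFrame
        one row per rendered (frame, cell): centroid and ellipse semi-axes, px.
    """

    cells: pd.DataFrame
    objects: pd.DataFrame
    fps: float
    frame_shape: tuple
    seed: object = None


def schedule_cells(
    cells: list[SimCell],
    geom: DeviceGeometry,
    windows: list[CreepWindow],
    kin: KinematicsParams,
    fps: float,
) -> list[CellPath]:
    """Assign cells to lanes round-robin with an enforced per-lane headway.

    One cell occupies a lane at a time: the next launch on a lane is the
    previous cell's final drawn frame plus ``headway_frames``.  A stalling
    occluder blocks its lane for the rest of the video.
    """
    n_lanes = geom.n_constrictions
    # frame 0 is kept cell-free so it can serve as a clean background reference
    next_free: list[int | None] = [1] * n_lanes
    paths: list[CellPath] = []
    lane_cursor = 0
    for cell in cells:
        for probe in range(n_lanes):
            lane = (lane_cursor + probe) % n_lanes
            if next_free[lane] is not None:
                break
        else:
            warnings.warn("all lanes blocked by occluders; remaining cells dropped")
            break
        lane_cursor = (lane + 1) % n_lanes
        cell = replace(cell, constriction_id=lane, launch_frame=next_free[lane])
        path = CellPath(cell, geom, windows[lane], kin, fps)
        if cell.stall:
            next_free[lane] = None
        else:
            next_free[lane] = path.last_frame + kin.headway_frames
        paths.append(path)
    return paths


def _frame_shape(geom: DeviceGeometry, paths: list[CellPath]) -> tuple[int, int]:
    ps = geom.pixel_size
    extent = float(geom.end_x().max()) * ps
    for p in paths:
        # rightmost drawn pixel along the whole path (the fully clamped
        # ellipse near the constriction end is the usual worst case)
        xs = np.append(np.linspace(p.x0, p.x_stop, 64), [min(p.end, p.x_stop)])
        for x in xs:
            extent = max(extent, x + p.shape_um(x)[0])
    width = int(math.ceil((extent + 5.0) / ps))
    y_max = float(np.max(geom.lane_y)) + (geom.lane_pitch / 2.0) / ps
    height = int(math.ceil(y_max))
    return height, width


def render(
    cells: list[SimCell],
    geom: DeviceGeometry | None = None,
    imaging: ImagingModel | None = None,
    n_frames: int | None = None,
    seed=None,
    kin: KinematicsParams | None = None,
    windows: list[CreepWindow] | None = None,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Render a scheduled cell list to frames plus ground truth.

    Returns
    -------
    frames : uint8 array (n_frames, H, W)
    truth : SyntheticTruth
        consistent with the rendered shapes; cells whose events do not fit in
        ``n_frames`` are truncated with a warning and flagged in the table.
    """
    geom = geom if geom is not None else build_geometry()
    imaging = imaging or ImagingModel()
    kin = kin or KinematicsParams()
    windows = windows or creep_window(geom)
    rng = np.random.default_rng(seed)

    paths = schedule_cells(cells, geom, windows, kin, imaging.fps)
    shape = _frame_shape(geom, paths)
    if n_frames is None:
        # trailing background worth one full event so the per-pixel median
        # background stays clean even in single-cell-per-lane videos
        last = max((p.last_frame for p in paths if not p.cell.stall), default=0)
        longest = max(
            (p.last_frame - p.cell.launch_frame for p in paths if not p.cell.stall),
            default=0,
        )
        n_frames = last + longest + 5
    truncated_ids = [
        p.cell.cell_id for p in paths if not p.cell.stall and p.last_frame >= n_frames
    ]
    if truncated_ids:
        warnings.warn(
            f"{len(truncated_ids)} cell(s) do not complete within n_frames={n_frames}; "
            "their records are truncated"
        )

    ps = geom.pixel_size
    frames = np.empty((n_frames, *shape), dtype=np.uint8)
    obj_rows = []
    cell_rows = []
    for p in paths:
        c = p.cell
        cell_rows.append(
            {
                "cell_id": c.cell_id,
                "population": c.population,
                "area_um2": c.area_um2,
                "c1": c.c1,
                "beta": c.beta,
                "t_creep": c.t_creep,
                "constriction_id": c.constriction_id,
                "launch_frame": c.launch_frame,
                "entry_frame": p.first_frame_at(p.w0),
                "creep_end_frame": p.first_frame_at(p.w1),
                "exit_frame": p.first_frame_at(p.end),
                "last_frame": p.last_frame if not c.stall else n_frames - 1,
                "stall": c.stall,
                "truncated": c.cell_id in truncated_ids,
            }
        )

    for f in range(n_frames):
        img = np.full(shape, imaging.background, dtype=float)
        for p in paths:
            c = p.cell
            if f < c.launch_frame or (not c.stall and f > p.last_frame):
                continue
            t = (f - c.launch_frame) / imaging.fps
            x_um = p.x_um(t)
            semi_flow, semi_trans = p.shape_um(x_um)
            cx = x_um / ps
            cy = float(geom.lane_y[c.constriction_id])
            rr, cc = draw_ellipse(cy, cx, semi_trans / ps, semi_flow / ps, shape=shape)
            img[rr, cc] = imaging.background + imaging.cell_contrast
            obj_rows.append(
                {
                    "frame": f,
                    "cell_id": c.cell_id,
                    "cx": cx,
                    "cy": cy,
                    "semi_x": semi_flow / ps,
                    "semi_y": semi_trans / ps,
                }
            )
        if imaging.blur_sigma > 0:
            img = ndi.gaussian_filter(img, imaging.blur_sigma)
        if imaging.noise_sigma > 0:
            img = img + rng.normal(0.0, imaging.noise_sigma, size=shape)
        frames[f] = np.clip(img, 0, 255).astype(np.uint8)

    objects = pd.DataFrame(
        obj_rows, columns=["frame", "cell_id", "cx", "cy", "semi_x", "semi_y"]
    )
    truth = SyntheticTruth(
        cells=pd.DataFrame(
            cell_rows,
            columns=[
                "cell_id", "population", "area_um2", "c1", "beta", "t_creep",
                "constriction_id", "launch_frame", "entry_frame", "creep_end_frame",
                "exit_frame", "last_frame", "stall", "truncated",
            ],
        ),
        objects=objects,
        fps=imaging.fps,
        frame_shape=shape,
        seed=seed,
    )
    return frames, truth


def simulate_video(
    specs: list[PopulationSpec] | None = None,
    n_cells: int = 20,
    geom: DeviceGeometry | None = None,
    imaging: ImagingModel | None = None,
    kin: KinematicsParams | None = None,
    seed=0,
    c2: float = DEFAULT_C2_UM,
    exact_fractions: bool = False,
    n_stalled: int = 0,
) -> tuple[np.ndarray, SyntheticTruth, DeviceGeometry]:
    """One-call simulator: sample a mixture, schedule, render.

    ``n_stalled`` appends that many occluder cells (they creep in and stall
    inside the constriction, blocking their lane) for fouling-QC scenarios.
    Deterministic in ``seed``.
    """
    specs = specs or default_population_specs()
    geom = geom if geom is not None else build_geometry()
    rng = np.random.default_rng(seed)
    cells = sample_population(
        specs, n_cells, seed=rng.integers(2**31), c2=c2, exact_fractions=exact_fractions
    )
    for k in range(n_stalled):
        proto = sample_population(specs, 1, seed=rng.integers(2**31), c2=c2)[0]
        cells.append(
            replace(proto, cell_id=len(cells), population="occluder", stall=True)
        )
    frames, truth = render(
        cells, geom, imaging, seed=rng.integers(2**31), kin=kin
    )
    return frames, truth, geom
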