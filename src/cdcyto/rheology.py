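"""Power-law rheology of cell entry into a microconstriction.

A cell of projected area A (um^2) squeezing into a constriction experiences a
radial compression

    eps_e = 1 - c2 / sqrt(A),        c2 = R_e * sqrt(pi)

where c2 converts area to the deformation rate imposed by the constriction
half-width R_e.  Treating the cell as a power-law viscoelastic material with
exponent beta (0 = elastic solid, 1 = viscous fluid; cells ~ 0.1-0.5), the
time to creep fully into the constriction is

    t_creep = c1 * eps_e**(1/beta),      c1 = (E / dP)**(1/beta) * t0

with E the cell elastic modulus, dP the mean pressure drop across the
constriction and t0 = 1 s the power-law timescale.  c1 (the "c1 index") is
therefore a per-cell stiffness measure: stiffer cells creep in more slowly.

This module provides the forward model, its per-cell inversion, the
closed-form group fit of c1 at fixed beta, grid selection of beta by fit
quality, conversion of c1 to an elastic modulus, and the optimal-size-range
criterion used to gate cell sizes for stiffness quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError

#: geometric constant for a 10 um constriction using the full printed width:
#: c2 = 10 * sqrt(pi) um.
DEFAULT_C2_UM = 10.0 * math.sqrt(math.pi)

#: mean pressure drop across one microconstriction (Pa) from fluidic simulation.
DEFAULT_DELTA_P_BAR = 162.82


def c2_from_width(width_um: float = 10.0) -> float:
    """Geometric constant c2 = width * sqrt(pi) (um).

    Note the printed convention feeds the *full* constriction width (10 um)
    into c2 even though R_e is nominally the half-width; pass
    ``geom.constriction_width / 2`` for the half-width convention.
    """
    return float(width_um) * math.sqrt(math.pi)


@dataclass
class StiffnessModelParams:
    """Parameters of the creep model.

    c2 : um
        Geometric area->deformation constant (default 10*sqrt(pi) = 17.7245).
    beta_grid : sequence
        Candidate power-law exponents for :func:`select_beta`.
    delta_p_bar : Pa
        Mean pressure drop across a constriction.
    t0 : s
        Power-law timescale, fixed at 1 s.
    """

    c2: float = DEFAULT_C2_UM
    beta_grid: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    delta_p_bar: float = DEFAULT_DELTA_P_BAR
    t0: float = 1.0

    def __post_init__(self):
        if not self.c2 > 0:
            raise ConfigurationError("c2 must be > 0")
        if not self.delta_p_bar > 0:
            raise ConfigurationError("delta_p_bar must be > 0")
        if len(self.beta_grid) == 0:
            raise ConfigurationError("beta_grid must be non-empty")
        for b in self.beta_grid:
            if not 0 < b <= 1:
                raise ConfigurationError(f"beta values must be in (0, 1], got {b}")


@dataclass
class RheologyFit:
    """Result of a group-level c1 fit at fixed beta."""

    c1_hat: float
    beta: float
    r_squared: float
    n_cells: int
    residuals: dict = field(default_factory=dict)


def epsilon_e(a_cell, c2: float = DEFAULT_C2_UM):
    """Deformation rate eps_e = 1 - c2/sqrt(A).

    Positive only for A > c2^2; non-deforming cells (A <= c2^2) return a
    non-positive value and are excluded from fits rather than raising.
    """
    a = np.asarray(a_cell, dtype=float)
    if np.any(a <= 0):
        raise InputError("cell area must be > 0")
    out = 1.0 - c2 / np.sqrt(a)
    return float(out) if out.ndim == 0 else out


def forward_creep_time(area, c1, beta, c2: float = DEFAULT_C2_UM):
    """Forward model: t_creep = c1 * (1 - c2/sqrt(A))**(1/beta).

    Strictly increasing in both ``area`` and ``c1``.

    Raises
    ------
    InputError
        if any area <= c2^2 (eps_e <= 0: the cell would not need to deform),
        c1 <= 0, or beta outside (0, 1].
    """
    area = np.asarray(area, dtype=float)
    c1 = np.asarray(c1, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(c1 <= 0):
        raise InputError("c1 must be > 0")
    if np.any((beta <= 0) | (beta > 1)):
        raise InputError("beta must be in (0, 1]")
    eps = 1.0 - c2 / np.sqrt(area)
    if np.any(eps <= 0):
        raise InputError(
            f"area must exceed c2^2 = {c2 ** 2:.4f} um^2 for the cell to deform"
        )
    t = c1 * eps ** (1.0 / beta)
    return float(t) if t.ndim == 0 else t


def c1_per_cell(t_creep, a_cell, beta: float, c2: float = DEFAULT_C2_UM):
    """Invert the forward model per cell: c1 = t_creep / eps_e**(1/beta).

    Vectorized; entries with t_creep <= 0, non-finite values, or A <= c2^2
    come back as NaN (excluded, not raised) so callers can count exclusions.
    """
    t = np.asarray(t_creep, dtype=float)
    a = np.asarray(a_cell, dtype=float)
    if not 0 < beta <= 1:
        raise InputError("beta must be in (0, 1]")
    t, a = np.broadcast_arrays(t, a)
    eps = np.where(a > 0, 1.0 - c2 / np.sqrt(np.where(a > 0, a, 1.0)), -1.0)
    valid = np.isfinite(t) & np.isfinite(a) & (t > 0) & (eps > 0)
    out = np.full(t.shape, np.nan)
    out[valid] = t[valid] / eps[valid] ** (1.0 / beta)
    return float(out) if out.ndim == 0 else out


def fit_group_c1(t_creep, a_cell, beta: float, c2: float = DEFAULT_C2_UM) -> RheologyFit:
    """Closed-form least-squares fit of c1 for one group of cells.

    Minimizes sum (t_i - c1 * x_i)^2 with x_i = eps_e,i**(1/beta) (no
    intercept; the model passes through the origin), giving
    c1 = sum(x t) / sum(x^2).  r^2 is reported as 1 - SS_res/SS_tot with
    SS_tot about the mean of t — conventions for no-intercept r^2 differ,
    this one keeps the value comparable across beta candidates.

    Cells with eps_e <= 0 or non-positive/non-finite t are excluded; at
    least 2 usable cells are required.
    """
    t = np.asarray(t_creep, dtype=float)
    a = np.asarray(a_cell, dtype=float)
    if not 0 < beta <= 1:
        raise InputError("beta must be in (0, 1]")
    eps = np.where(a > 0, 1.0 - c2 / np.sqrt(np.where(a > 0, a, 1.0)), -1.0)
    valid = np.isfinite(t) & np.isfinite(a) & (t > 0) & (eps > 0)
    t, eps = t[valid], eps[valid]
    n = int(valid.sum())
    if n < 2:
        raise InputError(f"need >= 2 cells with positive deformation rate, got {n}")
    x = eps ** (1.0 / beta)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise InputError("all predictors are zero; cannot fit c1")
    c1_hat = float(np.sum(x * t) / sxx)
    resid = t - c1_hat * x
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:  # all t identical: perfect iff residuals vanish (to float precision)
        r2 = 1.0 if ss_res <= 1e-20 * max(1.0, float(np.sum(t * t))) else -np.inf
    return RheologyFit(
        c1_hat=c1_hat,
        beta=float(beta),
        r_squared=float(r2),
        n_cells=n,
        residuals={
            "rmse": math.sqrt(ss_res / n),
            "max_abs": float(np.max(np.abs(resid))) if n else 0.0,
        },
    )


def select_beta(
    t_creep, a_cell, params: StiffnessModelParams | None = None
) -> tuple[float, dict[float, RheologyFit]]:
    """Fit every beta on the grid; return (best beta, per-beta fits).

    The best beta maximizes r^2; exact ties break toward the larger beta.
    """
    params = params or StiffnessModelParams()
    fits: dict[float, RheologyFit] = {}
    for b in params.beta_grid:
        fits[float(b)] = fit_group_c1(t_creep, a_cell, b, params.c2)
    best = max(fits, key=lambda b: (fits[b].r_squared, b))
    return best, fits


def elastic_modulus(c1, beta: float, delta_p_bar: float = DEFAULT_DELTA_P_BAR):
    """Elastic modulus from the stiffness index: E = dP * c1**beta (Pa).

    Inverse of c1 = (E/dP)**(1/beta); c1 = 1 returns dP for any beta.
    """
    c1 = np.asarray(c1, dtype=float)
    if np.any(c1 <= 0) or not 0 < beta <= 1 or delta_p_bar <= 0:
        raise InputError("elastic_modulus requires c1 > 0, beta in (0,1], dP > 0")
    out = delta_p_bar * c1**beta
    return float(out) if out.ndim == 0 else out


@dataclass
class SizeRangeResult:
    """Optimal size range: per-type intervals and their intersection."""

    per_type: dict
    size_min: float | None
    size_max: float | None

    @property
    def empty(self) -> bool:
        return self.size_min is None


def _line_band_interval(a_vals, e_vals):
    """Interval of A where the OLS line of E on A stays within mean(E) +/- SD(E),
    clipped to the observed A range.  Returns (lo, hi) or None."""
    a = np.asarray(a_vals, dtype=float)
    e = np.asarray(e_vals, dtype=float)
    a_lo, a_hi = float(a.min()), float(a.max())
    mu, sd = float(e.mean()), float(e.std(ddof=1)) if len(e) > 1 else 0.0
    if sd == 0:
        # degenerate rule: zero-variance E -> whole observed range
        return (a_lo, a_hi)
    slope, intercept = np.polyfit(a, e, 1)
    if slope == 0:
        return (a_lo, a_hi) if (mu - sd) <= intercept <= (mu + sd) else None
    bounds = sorted([(mu - sd - intercept) / slope, (mu + sd - intercept) / slope])
    lo, hi = max(bounds[0], a_lo), min(bounds[1], a_hi)
    return (float(lo), float(hi)) if lo <= hi else None


def optimal_size_range(records_by_type: dict) -> SizeRangeResult:
    """Size interval in which stiffness readout is unbiased by cell size.

    For each cell type, fit an ordinary least-squares line of per-cell elastic
    modulus E on cell area A and take the A interval where the fitted line
    lies within mean(E) +/- SD(E); the optimal range is the intersection of
    those intervals across types (empty intersection is returned explicitly).

    Parameters
    ----------
    records_by_type : dict
        type name -> (areas um^2, moduli Pa) arrays, >= 3 records each.
    """
    if len(records_by_type) < 2:
        raise InputError("need >= 2 cell types")
    per_type = {}
    lo, hi = -np.inf, np.inf
    for name, (a_vals, e_vals) in records_by_type.items():
        a_vals = np.asarray(a_vals, dtype=float)
        if len(a_vals) < 3:
            raise InputError(f"type {name!r} needs >= 3 records")
        interval = _line_band_interval(a_vals, e_vals)
        per_type[name] = interval
        if interval is None:
            lo, hi = np.inf, -np.inf
        else:
            lo, hi = max(lo, interval[0]), min(hi, interval[1])
    if lo > hi or not np.isfinite(lo):
        return SizeRangeResult(per_type, None, None)
    return SizeRangeResult(per_type, float(lo), float(hi))
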