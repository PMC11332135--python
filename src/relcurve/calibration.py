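"""Monte-Carlo error surfaces for the fitted C and planning intervals.

The accuracy of a fitted convergence coefficient depends on the number
of participants ``N``, the trials per participant ``L``, and the true
``C`` itself.  A calibration run simulates beta-binomial experiments
over a ``(C, N, L)`` grid, records the median and SD of the percent
error ``100 (C_hat - C)/C`` per cell, and the resulting surface backs
confidence intervals for pilot-study planning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

from .data import ScoreStats
from .fits import (
    MV_DENOMINATOR_GUARD,
    FitError,
    fit_direct,
    fit_linearized,
    fit_mv,
    trials_for_target,
)
from .simulate import simulate_trials
from .splithalf import rl_curve

__all__ = ["ErrorSurface", "PlanningInterval", "build_surface", "confidence_interval"]


@dataclass
class ErrorSurface:
    """Median/SD percent error of the fitted C over a ``(C, N, L)`` grid.

    ``median_pct_error[i, j, k]`` and ``sd_pct_error[i, j, k]`` summarise
    simulations at ``c_grid[i]``, ``n_grid[j]``, ``l_grid[k]``;
    ``guard_dropped`` counts simulations discarded per cell (MV
    denominator guard or otherwise invalid fits).  Cells where every
    simulation was discarded hold NaN.
    """

    c_grid: np.ndarray
    n_grid: np.ndarray
    l_grid: np.ndarray
    median_pct_error: np.ndarray
    sd_pct_error: np.ndarray
    n_sims: int
    guard_dropped: np.ndarray
    fit_method: str
    guard: float = MV_DENOMINATOR_GUARD
    seed: int | None = None

    def __post_init__(self):
        shape = (len(self.c_grid), len(self.n_grid), len(self.l_grid))
        for name in ("median_pct_error", "sd_pct_error", "guard_dropped"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} does not conform to the grid shape {shape}")
            setattr(self, name, arr)

    def to_dict(self) -> dict:
        return {
            "c_grid": np.asarray(self.c_grid).tolist(),
            "n_grid": np.asarray(self.n_grid).tolist(),
            "l_grid": np.asarray(self.l_grid).tolist(),
            "median_pct_error": self.median_pct_error.tolist(),
            "sd_pct_error": self.sd_pct_error.tolist(),
            "n_sims": int(self.n_sims),
            "guard_dropped": self.guard_dropped.tolist(),
            "fit_method": self.fit_method,
            "guard": self.guard,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ErrorSurface":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            c_grid=np.asarray(d["c_grid"], dtype=float),
            n_grid=np.asarray(d["n_grid"], dtype=float),
            l_grid=np.asarray(d["l_grid"], dtype=float),
            median_pct_error=np.asarray(d["median_pct_error"], dtype=float),
            sd_pct_error=np.asarray(d["sd_pct_error"], dtype=float),
            n_sims=d["n_sims"],
            guard_dropped=np.asarray(d["guard_dropped"], dtype=int),
            fit_method=d["fit_method"],
            guard=d["guard"],
            seed=d["seed"],
        )


def _mv_cell_errors(
    c_true: float, n: int, length: int, n_sims: int, guard: float, rng
) -> np.ndarray:
    """Vectorised percent errors of the MV fit for one grid cell.

    Proficiencies use ``alpha = beta = C/2``; scores are exact binomial
    means, which is distributionally identical to averaging a simulated
    trial matrix and far cheaper.
    """
    a = c_true / 2.0
    p = rng.beta(a, a, size=(n_sims, n))
    z = rng.binomial(length, p) / float(length)
    m = z.mean(axis=1)
    v = z.var(axis=1, ddof=1)
    bern = m - m * m
    den = v - bern / length
    num = bern - v
    valid = (den >= guard) & (num > 0)
    c_hat = np.full(n_sims, np.nan)
    c_hat[valid] = num[valid] / den[valid]
    return 100.0 * (c_hat - c_true) / c_true


def _curve_cell_errors(
    c_true: float,
    n: int,
    length: int,
    n_sims: int,
    fit_method: str,
    rng,
    n_perm_curve: int,
) -> np.ndarray:
    fit = fit_direct if fit_method == "direct" else fit_linearized
    a = c_true / 2.0
    errors = np.full(n_sims, np.nan)
    for i in range(n_sims):
        p = rng.beta(a, a, size=n)
        data = simulate_trials(p, length, rng)
        try:
            curve = rl_curve(data, "auto", n_perm=n_perm_curve, rng=rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c_hat = fit(curve).c
        except (FitError, RuntimeError, ValueError):
            continue
        errors[i] = 100.0 * (c_hat - c_true) / c_true
    return errors


def build_surface(
    c_grid,
    n_grid,
    l_grid,
    n_sims: int = 100,
    fit_method: str = "mv",
    rng: np.random.Generator | None = None,
    guard: float = MV_DENOMINATOR_GUARD,
    n_perm_curve: int = 200,
    seed: int | None = None,
) -> ErrorSurface:
    """Simulate beta-binomial experiments over a grid and record C errors.

    Per cell ``(C, N, L)``: draw ``N`` proficiencies from
    ``Beta(C/2, C/2)``, generate ``L`` Bernoulli trials each, fit C with
    the chosen method, and accumulate the percent error against the
    analytic ground truth.  MV fits falling foul of the denominator
    guard are discarded and counted, never imputed.
    """
    if fit_method not in ("direct", "linearized", "mv"):
        raise ValueError("fit_method must be direct, linearized or mv")
    c_grid = np.asarray(c_grid, dtype=float)
    n_grid = np.asarray(n_grid, dtype=int)
    l_grid = np.asarray(l_grid, dtype=int)
    if np.any(c_grid <= 0) or np.any(n_grid < 3) or np.any(l_grid < 2):
        raise ValueError("grids must be positive (N >= 3, L >= 2)")
    rng = np.random.default_rng(seed) if rng is None else rng

    shape = (c_grid.size, n_grid.size, l_grid.size)
    med = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    dropped = np.zeros(shape, dtype=int)
    for i, c_true in enumerate(c_grid):
        for j, n in enumerate(n_grid):
            for k, length in enumerate(l_grid):
                if fit_method == "mv":
                    errs = _mv_cell_errors(c_true, int(n), int(length), n_sims, guard, rng)
                else:
                    errs = _curve_cell_errors(
                        c_true, int(n), int(length), n_sims, fit_method, rng, n_perm_curve
                    )
                ok = np.isfinite(errs)
                dropped[i, j, k] = n_sims - int(ok.sum())
                if ok.sum() >= 2:
                    med[i, j, k] = np.median(errs[ok])
                    sd[i, j, k] = errs[ok].std(ddof=1)
                elif ok.sum() == 1:
                    med[i, j, k] = errs[ok][0]
                    sd[i, j, k] = np.nan
    return ErrorSurface(
        c_grid=c_grid,
        n_grid=n_grid.astype(float),
        l_grid=l_grid.astype(float),
        median_pct_error=med,
        sd_pct_error=sd,
        n_sims=n_sims,
        guard_dropped=dropped,
        fit_method=fit_method,
        guard=guard,
        seed=seed,
    )


class PlanningInterval(NamedTuple):
    c_low: float
    c_high: float
    c_debiased: float
    l_low: int | None
    l_high: int | None
    extrapolated: bool


def _bilinear(grid_x, grid_y, values, x, y):
    """Bilinear interpolation on a 2-D slice with clipping to the hull."""
    xi = np.clip(np.searchsorted(grid_x, x) - 1, 0, max(len(grid_x) - 2, 0))
    yi = np.clip(np.searchsorted(grid_y, y) - 1, 0, max(len(grid_y) - 2, 0))
    if len(grid_x) == 1:
        fx = 0.0
        xi = 0
        x1 = x0 = 0
    else:
        x0, x1 = xi, xi + 1
        fx = np.clip((x - grid_x[x0]) / (grid_x[x1] - grid_x[x0]), 0.0, 1.0)
    if len(grid_y) == 1:
        fy = 0.0
        y1 = y0 = 0
    else:
        y0, y1 = yi, yi + 1
        fy = np.clip((y - grid_y[y0]) / (grid_y[y1] - grid_y[y0]), 0.0, 1.0)
    v00, v01 = values[x0, y0], values[x0, y1]
    v10, v11 = values[x1, y0], values[x1, y1]
    return (
        v00 * (1 - fx) * (1 - fy)
        + v10 * fx * (1 - fy)
        + v01 * (1 - fx) * fy
        + v11 * fx * fy
    )


def confidence_interval(
    c_hat: float,
    n: int,
    t: int,
    surface: ErrorSurface,
    level: float = 0.95,
    r_target: float | None = None,
) -> PlanningInterval:
    """Simulation-calibrated interval for the true C (and trial counts).

    The surface's median and SD percent error are interpolated at the
    query point (nearest cell on the C axis, bilinear in N and L;
    queries outside the hull are clipped and flagged).  The point
    estimate is de-biased by the median error and the interval inverts
    ``C_hat = C (1 + e/100)`` at the normal quantiles of the error:

        C_bound = C_hat / (1 + (median +/- z * SD)/100).

    With ``r_target`` the C bounds are pushed through the trial-count
    prophecy to bound the trials needed for that reliability.
    """
    if not c_hat > 0:
        raise ValueError("c_hat must be positive")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    ci = int(np.argmin(np.abs(surface.c_grid - c_hat)))
    extrapolated = (
        n < surface.n_grid.min()
        or n > surface.n_grid.max()
        or t < surface.l_grid.min()
        or t > surface.l_grid.max()
        or c_hat < surface.c_grid.min() / 2
        or c_hat > surface.c_grid.max() * 2
    )
    med = float(
        _bilinear(surface.n_grid, surface.l_grid, surface.median_pct_error[ci], n, t)
    )
    sd = float(
        _bilinear(surface.n_grid, surface.l_grid, surface.sd_pct_error[ci], n, t)
    )
    if not (np.isfinite(med) and np.isfinite(sd)):
        raise ValueError(
            "calibration cells at the query point are unavailable (all "
            "simulations were discarded there); run a larger pilot or a "
            "denser calibration"
        )
    z = norm.ppf(0.5 + level / 2.0)
    c_debiased = c_hat / (1.0 + med / 100.0)
    lo_factor = 1.0 + (med + z * sd) / 100.0
    hi_factor = 1.0 + (med - z * sd) / 100.0
    c_low = c_hat / lo_factor if lo_factor > 0 else 0.0
    c_high = c_hat / hi_factor if hi_factor > 0 else np.inf
    l_low = l_high = None
    if r_target is not None:
        l_low = trials_for_target(r_target, max(c_low, 1e-9)).n_trials
        l_high = (
            trials_for_target(r_target, c_high).n_trials
            if np.isfinite(c_high)
            else None
        )
    return PlanningInterval(
        c_low=float(c_low),
        c_high=float(c_high),
        c_debiased=float(c_debiased),
        l_low=l_low,
        l_high=l_high,
        extrapolated=bool(extrapolated),
    )
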