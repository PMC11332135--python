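"""The convergence-coefficient model of reliability.

Split-half reliability of a mean score follows the hyperbolic curve

    R(L) = L / (L + C)

where ``L`` is the number of trials per half and ``C`` is the
convergence coefficient of the task (single-trial error variance over
true-score variance, a reformulation of the Spearman-Brown prophecy).
``C`` can be estimated three ways:

* **direct** - nonlinear least squares of the hyperbola on an observed
  reliability curve;
* **linearized** - ordinary least squares of ``1/R`` on ``1/L``
  (``1/R = 1 + C/L``); the slope is ``C`` and the intercept should be 1
  when trials are independent, so its deviation from 1 diagnoses
  learning or fatigue;
* **mv** (mean/variance) - for binary tasks only, a closed form from the
  mean and variance of participant scores, corrected for finite-trial
  sampling noise via the law of total variance.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares

from .data import ScoreStats
from .splithalf import RLCurve

__all__ = [
    "ConvergenceFit",
    "FitError",
    "SingularityError",
    "predict_r",
    "trials_for_target",
    "time_for_reliability",
    "fit_direct",
    "fit_linearized",
    "c_naive",
    "fit_mv",
]

#: denominator guard below which the MV closed form is numerically unstable
MV_DENOMINATOR_GUARD = 1e-3


class FitError(RuntimeError):
    """A convergence fit failed or produced a degenerate coefficient."""


class SingularityError(FitError):
    """The MV denominator fell below the stability guard.

    The score variance is indistinguishable from the binomial sampling
    floor; collect more trials and/or participants before fitting.
    """


@dataclass
class ConvergenceFit:
    """A fitted convergence coefficient with method and diagnostics.

    ``intercept`` (and its standard error) are defined only for the
    linearized method; an intercept far from 1 suggests trials are not
    independent (learning or fatigue).
    """

    c: float
    method: str  # "direct" | "linearized" | "mv"
    intercept: float | None = None
    intercept_se: float | None = None
    fit_residual: float | None = None
    inputs_summary: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if not (self.c > 0 and math.isfinite(self.c)):
            raise FitError(f"invalid convergence coefficient {self.c!r}")

    def predict(self, L):
        return predict_r(L, self.c)

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "C": self.c,
                "intercept": self.intercept,
                "intercept_se": self.intercept_se,
                "residual": self.fit_residual,
                **self.inputs_summary,
                "warnings": self.warnings,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# the model and its inverse
# ---------------------------------------------------------------------------

def predict_r(L, C):
    """Reliability of an L-trial score: ``R = L / (L + C)``."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0) or not C > 0:
        raise ValueError("L and C must be positive")
    out = L / (L + C)
    return float(out) if out.ndim == 0 else out


class TrialRequirement(NamedTuple):
    exact: float  #: real-valued solution of R = L/(L+C)
    n_trials: int  #: smallest integer trial count achieving the target


def trials_for_target(r_target: float, C: float) -> TrialRequirement:
    """Trials per half needed for a target reliability: ``L = C R/(1-R)``."""
    if not 0 < r_target < 1:
        raise ValueError(
            "target reliability must lie in (0, 1); reliability 1 requires "
            "infinitely many trials"
        )
    if not C > 0:
        raise ValueError("C must be positive")
    exact = C * r_target / (1.0 - r_target)
    return TrialRequirement(exact=exact, n_trials=int(math.ceil(exact - 1e-12)))


def time_for_reliability(C: float, r_target: float, seconds_per_trial: float) -> float:
    """Minutes of testing needed to reach a target reliability."""
    if not seconds_per_trial > 0:
        raise ValueError("seconds_per_trial must be positive")
    req = trials_for_target(r_target, C)
    return req.n_trials * seconds_per_trial / 60.0


# ---------------------------------------------------------------------------
# curve fits
# ---------------------------------------------------------------------------

def _curve_points(curve: RLCurve):
    ok = np.isfinite(curve.R_mean)
    return curve.L_values[ok].astype(float), curve.R_mean[ok], curve.R_sd[ok]


def fit_direct(curve: RLCurve, weighted: bool = False) -> ConvergenceFit:
    """Nonlinear least squares of ``R = L/(L+C)`` on a reliability curve.

    Unweighted by default; with ``weighted=True`` residuals are scaled by
    ``1/R_sd`` (points with zero SD fall back to the smallest positive SD).
    """
    L, R, sd = _curve_points(curve)
    if L.size < 3:
        raise FitError("need at least 3 defined curve points")
    if np.all(R > 1 - 1e-9):
        raise FitError("degenerate curve (R = 1 everywhere); C is indistinguishable from 0")
    # moment start: each point solves C = L(1-R)/R
    with np.errstate(divide="ignore"):
        c0 = np.median(np.where(R > 0, L * (1 - R) / np.maximum(R, 1e-9), 1.0))
    c0 = float(np.clip(c0, 1e-6, 1e6))
    if weighted:
        pos = sd[sd > 0]
        w = 1.0 / np.where(sd > 0, sd, pos.min() if pos.size else 1.0)
    else:
        w = np.ones_like(R)

    res = least_squares(
        lambda c: w * (R - L / (L + c[0])),
        x0=[c0],
        bounds=([1e-9], [np.inf]),
        xtol=1e-12,
        ftol=1e-12,
    )
    if not res.success:
        raise FitError(f"direct fit did not converge: {res.message}")
    c_hat = float(res.x[0])
    if c_hat <= 1e-8:
        raise FitError("degenerate direct fit (C at the zero boundary)")
    return ConvergenceFit(
        c=c_hat,
        method="direct",
        fit_residual=float(2 * res.cost),
        inputs_summary={
            "n": curve.n_participants,
            "L_grid": [int(v) for v in curve.L_values],
        },
    )


def fit_linearized(curve: RLCurve) -> ConvergenceFit:
    """OLS of ``1/R`` on ``1/L``; slope is C, intercept diagnoses drift."""
    import statsmodels.api as sm

    L, R, _ = _curve_points(curve)
    pos = R > 0
    notes = []
    if not pos.all():
        warnings.warn(
            f"dropping {int((~pos).sum())} curve point(s) with R <= 0 "
            "from the linearized fit"
        )
        notes.append(f"dropped {int((~pos).sum())} non-positive R points")
        L, R = L[pos], R[pos]
    if L.size < 3:
        raise FitError("need at least 3 curve points with R > 0")
    x = sm.add_constant(1.0 / L)
    model = sm.OLS(1.0 / R, x).fit()
    intercept, slope = model.params
    if slope <= 0:
        raise FitError(f"linearized fit produced non-positive C ({slope:.4g})")
    return ConvergenceFit(
        c=float(slope),
        method="linearized",
        intercept=float(intercept),
        intercept_se=float(model.bse[0]),
        fit_residual=float(model.ssr),
        inputs_summary={
            "n": curve.n_participants,
            "L_grid": [int(v) for v in L],
        },
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# mean/variance (closed-form) estimates for binary tasks
# ---------------------------------------------------------------------------

def c_naive(stats: ScoreStats) -> float:
    """Plug-in estimate ``C = (E[P] - E[P]^2)/Var(P) - 1``.

    Treats observed score statistics as if they were the latent
    proficiency statistics.  With finite-trial scores the binomial
    sampling noise inflates the variance, so this estimate is
    systematically biased *below* the true C; prefer :func:`fit_mv`.
    """
    m, v = stats.mean_z, stats.var_z
    if not 0 <= m <= 1:
        raise ValueError("mean outside [0, 1]; is the task binary?")
    if v <= 0:
        raise ValueError("variance must be positive")
    return (m - m * m) / v - 1.0


def fit_mv(
    stats: ScoreStats,
    guard: float = MV_DENOMINATOR_GUARD,
) -> ConvergenceFit:
    """Closed-form C from score mean/variance with total-variance correction.

    With scores averaged over ``T`` Bernoulli trials, the law of total
    variance gives ``Var(Z) = Var(P) + (E[Z] - E[Z]^2)/T`` (to leading
    order), hence

        C = (E[Z] - E[Z]^2 - Var(Z)) / (Var(Z) - (E[Z] - E[Z]^2)/T).

    Binary tasks only.  Raises :class:`SingularityError` when the
    denominator falls below ``guard`` (default 1e-3): the observed
    variance is then at the binomial sampling floor and C cannot be
    resolved.
    """
    m, v, t = stats.mean_z, stats.var_z, stats.n_trials_per_participant
    if not 0 <= m <= 1:
        raise ValueError("mean outside [0, 1]; the MV fit needs binary outcomes")
    if t < 2:
        raise ValueError("need at least 2 trials per participant")
    bern = m - m * m
    numerator = bern - v
    denominator = v - bern / t
    if denominator < guard:
        raise SingularityError(
            f"MV denominator {denominator:.3g} < {guard:g}: score variance is "
            "at the binomial sampling floor; collect more trials and/or "
            "participants"
        )
    if numerator <= 0:
        raise FitError(
            "score variance at or above the Bernoulli bound "
            f"(Var(Z)={v:.4g} >= E[Z](1-E[Z])={bern:.4g}); data look "
            "all-or-none and the model does not apply"
        )
    return ConvergenceFit(
        c=float(numerator / denominator),
        method="mv",
        inputs_summary={"n": stats.n_participants, "T": int(t)},
    )
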