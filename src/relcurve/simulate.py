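"""Synthetic beta-binomial trial data with known ground truth.

Participants draw a latent proficiency ``P ~ Beta(alpha, beta)`` and
produce independent Bernoulli(P) trials.  For this generative model the
convergence coefficient is known in closed form, ``C = alpha + beta``,
which makes these datasets the calibration standard for every estimator
in the package.  Session-to-session state changes (attention, arousal)
are emulated by perturbing each participant's proficiency with additive
Gaussian noise per session, clipped back to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data import ScoreStats, TrialMatrix

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "sample_proficiencies",
    "simulate_trials",
    "simulate_sessions",
    "random_null_data",
    "ground_truth_c",
    "beta_moment_fit",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Beta-population parameters and sampling sizes for one experiment.

    With ``session_noise_sd = 0`` the true convergence coefficient is
    ``alpha + beta`` exactly.
    """

    alpha: float
    beta: float
    n_participants: int
    n_trials: int
    session_noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("beta shape parameters must be positive")
        if self.n_participants < 1 or self.n_trials < 1:
            raise ValueError("need at least one participant and one trial")
        if self.session_noise_sd < 0:
            raise ValueError("session noise SD cannot be negative")

    @property
    def c_true(self) -> float:
        """Analytic convergence coefficient (valid when session noise is 0)."""
        return self.alpha + self.beta

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "n_participants": self.n_participants,
            "n_trials": self.n_trials,
            "session_noise_sd": self.session_noise_sd,
            "seed": self.seed,
            "c_true": self.c_true,
        }


def sample_proficiencies(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw N i.i.d. Beta(alpha, beta) proficiencies."""
    rng = spec.rng() if rng is None else rng
    return rng.beta(spec.alpha, spec.beta, size=spec.n_participants)


def _trial_meta(n_trials: int, session: str, form: str = "sim") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "form": [form] * n_trials,
            "session": [session] * n_trials,
            "trial": np.arange(n_trials),
        }
    )


def simulate_trials(
    proficiencies: np.ndarray,
    n_trials: int,
    rng: np.random.Generator | None = None,
    session: str = "1",
    task_name: str = "synthetic",
) -> TrialMatrix:
    """Independent Bernoulli(P_i) trials for each participant (no learning)."""
    rng = np.random.default_rng() if rng is None else rng
    p = np.asarray(proficiencies, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proficiencies must lie in [0, 1]")
    outcomes = (rng.random((p.size, n_trials)) < p[:, None]).astype(float)
    return TrialMatrix(
        outcomes=outcomes,
        participant_ids=np.arange(p.size),
        trial_meta=_trial_meta(n_trials, session),
        task_name=task_name,
        binary=True,
    )


def simulate_sessions(
    spec: SyntheticSpec,
    n_sessions: int,
    rng: np.random.Generator | None = None,
) -> list[TrialMatrix]:
    """Per-session matrices with session-perturbed proficiencies.

    Session ``s`` uses ``P_i,s = clip(P_i + eps_i,s, 0, 1)`` with
    ``eps ~ Normal(0, session_noise_sd^2)`` drawn independently per
    participant and session; each matrix carries ``n_trials`` Bernoulli
    trials.  Combine with :func:`relcurve.data.concat_sessions` for the
    test-retest operations.
    """
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    rng = spec.rng() if rng is None else rng
    base = sample_proficiencies(spec, rng)
    out = []
    for s in range(n_sessions):
        eps = rng.normal(0.0, spec.session_noise_sd, size=base.size)
        p_s = np.clip(base + eps, 0.0, 1.0)
        out.append(
            simulate_trials(p_s, spec.n_trials, rng, session=str(s + 1))
        )
    return out


def random_null_data(
    n_participants: int,
    n_trials: int,
    p: float = 0.5,
    rng: np.random.Generator | None = None,
) -> TrialMatrix:
    """Structureless i.i.d. Bernoulli(p) data (no participant effects).

    Split-half reliability of such data has expectation 0; its spread
    sets the noise floor of the permutation estimator.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    outcomes = (rng.random((n_participants, n_trials)) < p).astype(float)
    return TrialMatrix(
        outcomes=outcomes,
        participant_ids=np.arange(n_participants),
        trial_meta=_trial_meta(n_trials, "1"),
        task_name="null",
        binary=True,
    )


class GroundTruth(NamedTuple):
    analytic: float  #: alpha + beta
    empirical: float  #: large-N mean/variance estimate on exact proficiencies


def ground_truth_c(
    alpha: float,
    beta: float,
    n_large: int = 10**6,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Ground-truth C for a Beta(alpha, beta) proficiency population.

    Returns both the analytic value ``alpha + beta`` and an empirical
    estimate from the mean/variance identity applied to ``n_large``
    exact proficiency draws (no trial sampling, so no finite-trial
    correction is needed); calibration can use either.
    """
    if not (alpha > 0 and beta > 0):
        raise ValueError("beta shape parameters must be positive")
    rng = np.random.default_rng() if rng is None else rng
    p = rng.beta(alpha, beta, size=int(n_large))
    m = float(p.mean())
    v = float(p.var(ddof=1))
    empirical = (m - m * m) / v - 1.0
    return GroundTruth(analytic=float(alpha + beta), empirical=empirical)


def beta_moment_fit(scores: np.ndarray, n_trials: int) -> tuple[float, float]:
    """Method-of-moments beta shapes from finite-trial binary scores.

    The latent proficiency variance is recovered by subtracting the
    binomial sampling term: ``Var(P) = Var(Z) - E[Z](1 - E[Z])/T``.
    Useful for emulating a real task in simulation.  Raises when the
    corrected variance is non-positive (data indistinguishable from
    structureless noise).
    """
    z = np.asarray(scores, dtype=float)
    if np.any((z < 0) | (z > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if n_trials < 2:
        raise ValueError("need at least 2 trials per participant")
    m = float(z.mean())
    var_c = float(z.var(ddof=1)) - m * (1 - m) / n_trials
    if var_c <= 0:
        raise ValueError(
            "corrected proficiency variance is non-positive; the scores are "
            "indistinguishable from pure binomial noise"
        )
    nu = m * (1 - m) / var_c - 1.0
    if nu <= 0:
        raise ValueError("corrected variance exceeds the Bernoulli bound")
    return m * nu, (1 - m) * nu
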