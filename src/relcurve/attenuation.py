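"""Reliability-driven attenuation of correlations and test-retest ceilings.

Imperfect reliability shrinks observed between-measure correlations
toward zero (Spearman's attenuation): with reliabilities ``R_a, R_b``
the expected observed correlation is ``r_true * sqrt(R_a * R_b)``.  The
same identity, run in reverse on within- vs across-session
correlations, yields the *test-retest ceiling* - the value a test-retest
reliability curve converges to at infinite trials, which sits below 1
whenever performance genuinely changes between sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data import TrialMatrix
from .fits import fit_direct, predict_r, trials_for_target
from .splithalf import _column_samples, _pearson_columns, _Scorer, rl_curve

__all__ = [
    "AttenuationResult",
    "CeilingResult",
    "spearman_attenuation",
    "correlate_at_reliability",
    "testretest_ceiling",
    "session_outlier_filter",
]


def spearman_attenuation(r_true: float, r_a: float, r_b: float) -> float:
    """Expected observed correlation: ``r_true * sqrt(R_a * R_b)``."""
    if not (0 < r_a <= 1 and 0 < r_b <= 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    if not -1 <= r_true <= 1:
        raise ValueError("correlation must lie in [-1, 1]")
    return r_true * float(np.sqrt(r_a * r_b))


@dataclass
class AttenuationResult:
    """Observed-correlation distributions per targeted reliability level."""

    reliability_levels: np.ndarray  #: requested reliability per level
    effective_r_a: np.ndarray  #: reliability achieved by the integer L, task a
    effective_r_b: np.ndarray
    l_a: np.ndarray  #: trials subsampled per level, task a
    l_b: np.ndarray
    mean_r: np.ndarray
    sd_r: np.ndarray
    r_full: float  #: correlation using all available trials of both tasks
    predicted_r: np.ndarray  #: attenuation prediction r_full * sqrt(Ra*Rb)
    n_resamples: int
    n_participants: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reliability": self.reliability_levels,
                "L_a": self.l_a,
                "L_b": self.l_b,
                "mean_r": self.mean_r,
                "sd_r": self.sd_r,
                "predicted_r": self.predicted_r,
            }
        )


def _align_shared(task_a: TrialMatrix, task_b: TrialMatrix):
    shared = task_a.participant_ids[
        np.isin(task_a.participant_ids, task_b.participant_ids)
    ]
    if shared.size < 3:
        raise ValueError("need at least 3 participants shared between tasks")
    return task_a.select_participants(shared), task_b.select_participants(shared), shared


def correlate_at_reliability(
    task_a: TrialMatrix,
    task_b: TrialMatrix,
    r_levels,
    n_resamples: int = 1000,
    rng: np.random.Generator | None = None,
    c_a: float | None = None,
    c_b: float | None = None,
    n_perm_curve: int = 500,
) -> AttenuationResult:
    """Between-task correlation as a function of per-task reliability.

    For each reliability level the required trial counts are obtained
    from each task's convergence coefficient (fitted directly from its
    reliability curve unless supplied); per resample that many trials
    are drawn per task, scored, and the two score vectors are
    Pearson-correlated across the shared participants.  The attenuation
    prediction uses the full-data correlation and the reliabilities
    actually achieved by the integer trial counts.  Levels needing more
    trials than available are dropped with a warning.
    """
    rng = np.random.default_rng() if rng is None else rng
    a, b, shared = _align_shared(task_a, task_b)
    if c_a is None:
        c_a = fit_direct(rl_curve(a, "auto", n_perm=n_perm_curve, rng=rng)).c
    if c_b is None:
        c_b = fit_direct(rl_curve(b, "auto", n_perm=n_perm_curve, rng=rng)).c

    scorer_a, scorer_b = _Scorer(a.outcomes), _Scorer(b.outcomes)
    full_a = np.nanmean(a.outcomes, axis=1)
    full_b = np.nanmean(b.outcomes, axis=1)
    r_full = float(np.corrcoef(full_a, full_b)[0, 1])

    levels, eff_a, eff_b, las, lbs, means, sds, preds = ([] for _ in range(8))
    for level in np.atleast_1d(np.asarray(r_levels, dtype=float)):
        la = trials_for_target(level, c_a).n_trials
        lb = trials_for_target(level, c_b).n_trials
        if la > a.n_trials or lb > b.n_trials:
            warnings.warn(
                f"reliability level {level:.2f} needs L_a={la}, L_b={lb} "
                f"trials (available {a.n_trials}, {b.n_trials}); dropped"
            )
            continue
        (pick_a,) = _column_samples(rng, np.arange(a.n_trials), (la,), n_resamples)
        (pick_b,) = _column_samples(rng, np.arange(b.n_trials), (lb,), n_resamples)
        r = _pearson_columns(scorer_a.scores(pick_a), scorer_b.scores(pick_b))
        ok = np.isfinite(r)
        ra, rb = predict_r(la, c_a), predict_r(lb, c_b)
        levels.append(level)
        eff_a.append(ra)
        eff_b.append(rb)
        las.append(la)
        lbs.append(lb)
        means.append(float(r[ok].mean()))
        sds.append(float(r[ok].std(ddof=1)) if ok.sum() > 1 else 0.0)
        preds.append(spearman_attenuation(r_full, ra, rb))
    if not levels:
        raise ValueError("no reliability level was attainable with the data")
    return AttenuationResult(
        reliability_levels=np.array(levels),
        effective_r_a=np.array(eff_a),
        effective_r_b=np.array(eff_b),
        l_a=np.array(las, dtype=int),
        l_b=np.array(lbs, dtype=int),
        mean_r=np.array(means),
        sd_r=np.array(sds),
        r_full=r_full,
        predicted_r=np.array(preds),
        n_resamples=n_resamples,
        n_participants=int(shared.size),
    )


def session_outlier_filter(*score_vectors, k: float = 2.0) -> np.ndarray:
    """Mask of participants whose session score changes are not outlying.

    For each pair of sessions, participants whose score difference
    deviates from the mean difference by more than ``k`` SD are flagged;
    the union of flags over all pairwise comparisons is dropped.
    Returns a boolean retain-mask aligned with the score vectors.
    """
    if len(score_vectors) < 2:
        raise ValueError("need at least two score vectors")
    arrays = [np.asarray(v, dtype=float) for v in score_vectors]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("score vectors must be aligned")
    if n < 3:
        raise ValueError("need at least 3 participants")
    drop = np.zeros(n, dtype=bool)
    if not np.isfinite(k):
        return ~drop
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            d = arrays[i] - arrays[j]
            sd = d.std(ddof=1)
            if sd == 0:
                continue
            drop |= np.abs(d - d.mean()) > k * sd
    return ~drop


class CeilingResult(NamedTuple):
    ceiling: float  #: r_across / sqrt(r_within_a * r_within_b)
    r_within_a: float
    r_within_b: float
    r_across: float
    L: int
    n_retained: int


def testretest_ceiling(
    data: TrialMatrix,
    session_a,
    session_b,
    L: int | None = None,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    outlier_k: float = 2.0,
    randomize_sessions: bool = False,
) -> CeilingResult:
    """Infinite-trials convergence value of the test-retest curve.

    Computed as ``r_across / sqrt(r_within_a * r_within_b)`` where the
    within-session terms are split-half correlations inside each session
    and the across term is the test-retest correlation, all at the same
    matched half-length ``L`` (default: half the smaller session) and
    averaged over ``n_perm`` resamples.  Under the additive
    session-noise model the matched-L ratio equals
    ``Var(P) / (Var(P) + sigma_session^2)`` at every L, which is exactly
    the curve's infinite-trials limit; the ratio is therefore reported
    as the convergence value.

    Participants whose between-session score change is an outlier
    (``outlier_k`` SD on the session difference) are removed first.
    With ``randomize_sessions`` the session labels are shuffled over
    trial columns per resample, a sanity mode whose ceiling is 1 up to
    Monte-Carlo error.
    """
    rng = np.random.default_rng() if rng is None else rng
    cols_a = data.session_columns(session_a)
    cols_b = data.session_columns(session_b)

    with np.errstate(invalid="ignore"):
        sa = np.nanmean(data.outcomes[:, cols_a], axis=1)
        sb = np.nanmean(data.outcomes[:, cols_b], axis=1)
    retain = session_outlier_filter(sa, sb, k=outlier_k)
    work = data.select_participants(retain)

    if L is None:
        L = min(cols_a.size, cols_b.size) // 2
    if L < 1 or 2 * L > min(cols_a.size, cols_b.size):
        raise ValueError(
            f"need 2*L <= min session size ({min(cols_a.size, cols_b.size)}); got L={L}"
        )
    scorer = _Scorer(work.outcomes)
    r_wa = np.empty(n_perm)
    r_wb = np.empty(n_perm)
    r_x = np.empty(n_perm)
    # batched: one "resample block" per call keeps memory flat
    ca, cb = cols_a, cols_b
    if randomize_sessions:
        pool = np.concatenate([cols_a, cols_b])
        perm = rng.permutation(pool)
        ca, cb = perm[: cols_a.size], perm[cols_a.size :]
    a1, a2 = _column_samples(rng, ca, (L, L), n_perm)
    b1, b2 = _column_samples(rng, cb, (L, L), n_perm)
    s_a1, s_a2 = scorer.scores(a1), scorer.scores(a2)
    s_b1, s_b2 = scorer.scores(b1), scorer.scores(b2)
    r_wa = _pearson_columns(s_a1, s_a2)
    r_wb = _pearson_columns(s_b1, s_b2)
    r_x = _pearson_columns(s_a1, s_b1)
    m_wa = float(np.nanmean(r_wa))
    m_wb = float(np.nanmean(r_wb))
    m_x = float(np.nanmean(r_x))
    if m_wa <= 0 or m_wb <= 0:
        raise ValueError(
            "non-positive within-session reliability; the ceiling is undefined"
        )
    return CeilingResult(
        ceiling=m_x / float(np.sqrt(m_wa * m_wb)),
        r_within_a=m_wa,
        r_within_b=m_wb,
        r_across=m_x,
        L=int(L),
        n_retained=int(retain.sum()),
    )
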