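"""Permutation split-halves and test-retest reliability curves.

Reliability ``R`` at half-length ``L`` is estimated as the mean Pearson
correlation, over many random resamples, between participant score
vectors computed from two disjoint ``L``-trial subsets.  The same trial
columns are drawn for every participant within a resample (a split by
trials, which preserves item effects).  Test-retest reliability is the
special split in which the two subsets come from different sessions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrialMatrix

__all__ = [
    "RLCurve",
    "ConstantScoreError",
    "rl_point",
    "rl_curve",
    "testretest_curve",
    "averaged_testretest",
    "curve_difference_test",
    "auto_grid",
]


class ConstantScoreError(RuntimeError):
    """All resamples produced a constant score vector (correlation undefined)."""


@dataclass
class RLCurve:
    """Reliability as a function of trials per half.

    ``R_mean[i]`` / ``R_sd[i]`` are the mean and SD of the correlation
    distribution at ``L_values[i]``; ``n_used[i]`` counts resamples with
    a defined correlation (constant-score resamples are dropped).
    """

    L_values: np.ndarray
    R_mean: np.ndarray
    R_sd: np.ndarray
    n_used: np.ndarray
    n_perm: int
    mode: str  # "pooled" | "testretest"
    n_participants: int

    def __post_init__(self):
        self.L_values = np.asarray(self.L_values, dtype=int)
        self.R_mean = np.asarray(self.R_mean, dtype=float)
        self.R_sd = np.asarray(self.R_sd, dtype=float)
        self.n_used = np.asarray(self.n_used, dtype=int)
        if np.any(np.diff(self.L_values) <= 0):
            raise ValueError("L_values must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "L": self.L_values,
                "R_mean": self.R_mean,
                "R_sd": self.R_sd,
                "n_used": self.n_used,
            }
        )

    def meta(self, **extra) -> dict:
        return {
            "mode": self.mode,
            "n_perm": int(self.n_perm),
            "n_participants": int(self.n_participants),
            **extra,
        }

    def write(self, csv_path, json_path=None, **meta) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.meta(**meta), fh, indent=2)


# ---------------------------------------------------------------------------
# vectorised internals
# ---------------------------------------------------------------------------

def _column_samples(rng, cols: np.ndarray, sizes, n_perm: int):
    """Draw, per resample, disjoint subsets of ``cols`` of the given sizes.

    Returns a list of ``(n_perm, size)`` integer arrays of column indices
    (one per requested size, mutually disjoint within a resample).
    """
    k = cols.size
    order = np.argsort(rng.random((n_perm, k)), axis=1)
    picks, start = [], 0
    for size in sizes:
        picks.append(cols[order[:, start : start + size]])
        start += size
    return picks


def _indicator(sample: np.ndarray, n_cols: int) -> np.ndarray:
    """(n_perm, T) 0/1 matrix marking the sampled columns of each resample."""
    n_perm, size = sample.shape
    m = np.zeros((n_perm, n_cols))
    m[np.repeat(np.arange(n_perm), size), sample.ravel()] = 1.0
    return m


class _Scorer:
    """Batched mean-score computation over column subsets of one matrix."""

    def __init__(self, outcomes: np.ndarray):
        self.has_missing = bool(np.isnan(outcomes).any())
        self.values = np.nan_to_num(outcomes, nan=0.0)
        self.counts = np.isfinite(outcomes).astype(float) if self.has_missing else None
        self.n_cols = outcomes.shape[1]

    def scores(self, sample: np.ndarray) -> np.ndarray:
        """(N, n_perm) mean scores for each resample's column subset."""
        m = _indicator(sample, self.n_cols)
        sums = self.values @ m.T
        if self.has_missing:
            cnt = self.counts @ m.T
            with np.errstate(invalid="ignore", divide="ignore"):
                out = sums / cnt
            out[cnt == 0] = np.nan
            return out
        return sums / sample.shape[1]


def _rank_columns(a: np.ndarray) -> np.ndarray:
    """Column-wise average ranks (for the Spearman option)."""
    from scipy.stats import rankdata

    return rankdata(a, axis=0)


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two (N, n_perm) arrays.

    Columns with zero variance (or with missing scores) yield NaN.
    """
    bad = np.isnan(a).any(axis=0) | np.isnan(b).any(axis=0)
    if bad.any():
        # exclude participants with undefined scores pairwise, per resample
        r = np.empty(a.shape[1])
        good_cols = ~bad
        if good_cols.any():
            r[good_cols] = _pearson_columns(a[:, good_cols], b[:, good_cols])
        for j in np.flatnonzero(bad):
            ok = np.isfinite(a[:, j]) & np.isfinite(b[:, j])
            if ok.sum() < 3:
                r[j] = np.nan
                continue
            x, y = a[ok, j], b[ok, j]
            xc, yc = x - x.mean(), y - y.mean()
            den = np.sqrt((xc @ xc) * (yc @ yc))
            r[j] = xc @ yc / den if den > 0 else np.nan
        return r
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = np.einsum("ij,ij->j", ac, bc)
    den = np.sqrt(
        np.einsum("ij,ij->j", ac, ac) * np.einsum("ij,ij->j", bc, bc)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def _correlate(sa: np.ndarray, sb: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        sa, sb = _rank_columns(sa), _rank_columns(sb)
    return _pearson_columns(sa, sb)


def _summarise(r: np.ndarray, context: str):
    defined = np.isfinite(r)
    n_used = int(defined.sum())
    if n_used == 0:
        raise ConstantScoreError(
            f"every resample had an undefined correlation ({context}); "
            "score vectors are constant across participants"
        )
    if n_used < r.size:
        warnings.warn(
            f"{r.size - n_used} of {r.size} resamples had undefined "
            f"correlations and were dropped ({context})"
        )
    vals = r[defined]
    sd = float(vals.std(ddof=1)) if n_used > 1 else 0.0
    return float(vals.mean()), sd, n_used


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def rl_point(
    data: TrialMatrix,
    L: int,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    columns: np.ndarray | None = None,
    method: str = "pearson",
):
    """One point of the pooled split-halves curve.

    Draws two disjoint ``L``-trial subsets (same columns for every
    participant), scores each half, and Pearson-correlates the two score
    vectors across participants; repeated ``n_perm`` times.

    Returns ``(R_mean, R_sd, samples)`` where ``samples`` is the raw
    correlation sample (NaN for undefined resamples).
    """
    rng = np.random.default_rng() if rng is None else rng
    cols = np.arange(data.n_trials) if columns is None else np.asarray(columns)
    if data.n_participants < 3:
        raise ValueError("need at least 3 participants")
    if L < 1 or 2 * L > cols.size:
        raise ValueError(f"need 2*L <= {cols.size} usable trials; got L={L}")
    scorer = _Scorer(data.outcomes)
    half_a, half_b = _column_samples(rng, cols, (L, L), n_perm)
    r = _correlate(scorer.scores(half_a), scorer.scores(half_b), method)
    mean, sd, n_used = _summarise(r, f"pooled split at L={L}")
    return mean, sd, r


def auto_grid(max_L: int, n_points: int = 12) -> np.ndarray:
    """Roughly log-spaced half-lengths from 2 to ``max_L`` (>= 10 points
    when the range allows)."""
    if max_L < 2:
        raise ValueError("need max_L >= 2")
    if max_L - 1 <= n_points:
        return np.arange(2, max_L + 1)
    grid = np.unique(np.round(np.geomspace(2, max_L, n_points)).astype(int))
    # geomspace rounding can merge small values; backfill to keep >= 10 points
    want = min(n_points, max_L - 1)
    extra = 2
    while grid.size < want and extra <= max_L:
        grid = np.unique(np.concatenate([grid, [extra]]))
        extra += 1
    return grid


def rl_curve(
    data: TrialMatrix,
    L_grid="auto",
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    method: str = "pearson",
) -> RLCurve:
    """Pooled split-halves reliability curve over a grid of half-lengths.

    The grid tops out at ``floor(T/2)`` (the largest disjoint split).
    """
    rng = np.random.default_rng() if rng is None else rng
    max_L = data.n_trials // 2
    if isinstance(L_grid, str) and L_grid == "auto":
        grid = auto_grid(max_L)
    else:
        grid = np.unique(np.asarray(L_grid, dtype=int))
        bad = grid[(grid < 1) | (grid > max_L)]
        if bad.size:
            raise ValueError(
                f"grid values outside [1, floor(T/2)={max_L}]: {list(bad)}"
            )
    means, sds, used = [], [], []
    for L in grid:
        m, s, r = rl_point(data, int(L), n_perm, rng, method=method)
        means.append(m)
        sds.append(s)
        used.append(int(np.isfinite(r).sum()))
    return RLCurve(
        L_values=grid,
        R_mean=np.array(means),
        R_sd=np.array(sds),
        n_used=np.array(used),
        n_perm=n_perm,
        mode="pooled",
        n_participants=data.n_participants,
    )


def _session_cols(data: TrialMatrix, label) -> np.ndarray:
    return data.session_columns(label)


def testretest_point(
    data: TrialMatrix,
    session_a,
    session_b,
    L: int,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    method: str = "pearson",
):
    """One test-retest point: ``L`` trials from each session, correlated."""
    rng = np.random.default_rng() if rng is None else rng
    cols_a = _session_cols(data, session_a)
    cols_b = _session_cols(data, session_b)
    if L < 1 or L > min(cols_a.size, cols_b.size):
        raise ValueError(
            f"L={L} exceeds session sizes ({cols_a.size}, {cols_b.size})"
        )
    scorer = _Scorer(data.outcomes)
    (pick_a,) = _column_samples(rng, cols_a, (L,), n_perm)
    (pick_b,) = _column_samples(rng, cols_b, (L,), n_perm)
    r = _correlate(scorer.scores(pick_a), scorer.scores(pick_b), method)
    mean, sd, n_used = _summarise(r, f"test-retest at L={L}")
    return mean, sd, r


def testretest_curve(
    data: TrialMatrix,
    session_a,
    session_b,
    L_grid="auto",
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    method: str = "pearson",
) -> RLCurve:
    """Test-retest reliability curve between two sessions.

    Per resample one ``L``-subset is drawn (without replacement) within
    each session; the two subsets come from disjoint trial pools, so no
    cross-session disjointness constraint applies.
    """
    rng = np.random.default_rng() if rng is None else rng
    cols_a = _session_cols(data, session_a)
    cols_b = _session_cols(data, session_b)
    max_L = min(cols_a.size, cols_b.size)
    if isinstance(L_grid, str) and L_grid == "auto":
        grid = auto_grid(max_L)
    else:
        grid = np.unique(np.asarray(L_grid, dtype=int))
        bad = grid[(grid < 1) | (grid > max_L)]
        if bad.size:
            raise ValueError(f"grid values outside [1, {max_L}]: {list(bad)}")
    means, sds, used = [], [], []
    for L in grid:
        m, s, r = testretest_point(data, session_a, session_b, int(L), n_perm, rng, method)
        means.append(m)
        sds.append(s)
        used.append(int(np.isfinite(r).sum()))
    return RLCurve(
        L_values=grid,
        R_mean=np.array(means),
        R_sd=np.array(sds),
        n_used=np.array(used),
        n_perm=n_perm,
        mode="testretest",
        n_participants=data.n_participants,
    )


def averaged_testretest(
    datasets: dict,
    group_a: list,
    group_b: list,
    L_grid="auto",
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> RLCurve:
    """Multi-day test-retest: average per-day scores within each day group.

    ``datasets`` maps day labels to per-day :class:`TrialMatrix` objects;
    ``group_a`` / ``group_b`` name disjoint day sets.  Per resample, ``L``
    trials are drawn from each named day, the per-day scores within a
    group are averaged to one score per participant, and the two group
    scores are correlated.  Averaging over days suppresses day-specific
    (transient state) noise, so the curve rises with group size.
    """
    rng = np.random.default_rng() if rng is None else rng
    if set(group_a) & set(group_b):
        raise ValueError("day groups must be disjoint")
    days = list(group_a) + list(group_b)
    missing = [d for d in days if d not in datasets]
    if missing:
        raise KeyError(f"unknown day labels: {missing}")
    shared = datasets[days[0]].participant_ids
    for d in days[1:]:
        shared = shared[np.isin(shared, datasets[d].participant_ids)]
    if shared.size < 3:
        raise ValueError("need at least 3 participants present on all days")
    mats = {d: datasets[d].select_participants(shared) for d in days}
    max_L = min(mats[d].n_trials for d in days)
    if isinstance(L_grid, str) and L_grid == "auto":
        grid = auto_grid(max_L)
    else:
        grid = np.unique(np.asarray(L_grid, dtype=int))
        bad = grid[(grid < 1) | (grid > max_L)]
        if bad.size:
            raise ValueError(f"grid values outside [1, {max_L}]: {list(bad)}")
    scorers = {d: _Scorer(mats[d].outcomes) for d in days}
    means, sds, used = [], [], []
    for L in grid:
        group_scores = []
        for group in (group_a, group_b):
            acc = None
            for d in group:
                (pick,) = _column_samples(
                    rng, np.arange(mats[d].n_trials), (int(L),), n_perm
                )
                s = scorers[d].scores(pick)
                acc = s if acc is None else acc + s
            group_scores.append(acc / len(group))
        r = _pearson_columns(group_scores[0], group_scores[1])
        m, s, n_used = _summarise(r, f"averaged test-retest at L={L}")
        means.append(m)
        sds.append(s)
        used.append(n_used)
    return RLCurve(
        L_values=grid,
        R_mean=np.array(means),
        R_sd=np.array(sds),
        n_used=np.array(used),
        n_perm=n_perm,
        mode="testretest",
        n_participants=int(shared.size),
    )


def curve_difference_test(
    data: TrialMatrix,
    session_a,
    session_b,
    L: int,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    n_inner: int = 100,
    two_sided: bool = False,
):
    """Permutation test of pooled-minus-test-retest reliability at one L.

    The observed statistic is (pooled split-halves R) - (test-retest R),
    each a mean over ``n_inner`` resamples at half-length ``L``.  The
    null is built by shuffling which trial columns carry which session
    label (same label counts, same shuffle for every participant) and
    recomputing the statistic ``n_perm`` times.  The one-sided p-value is
    the add-one-smoothed fraction of null statistics >= observed, so the
    smallest reportable value is ``1/(n_perm+1)`` (reported as an upper
    bound when the observed statistic exceeds the whole null sample).

    Returns ``(p_value, observed, null_distribution)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    cols_a = _session_cols(data, session_a)
    cols_b = _session_cols(data, session_b)
    if L > min(cols_a.size, cols_b.size) or 2 * L > cols_a.size + cols_b.size:
        raise ValueError(f"L={L} exceeds per-session trial counts")
    pool = np.concatenate([cols_a, cols_b])
    scorer = _Scorer(data.outcomes)

    def statistic(ca: np.ndarray, cb: np.ndarray) -> float:
        both = np.concatenate([ca, cb])
        ha, hb = _column_samples(rng, both, (L, L), n_inner)
        r_pool = _pearson_columns(scorer.scores(ha), scorer.scores(hb))
        (pa,) = _column_samples(rng, ca, (L,), n_inner)
        (pb,) = _column_samples(rng, cb, (L,), n_inner)
        r_tr = _pearson_columns(scorer.scores(pa), scorer.scores(pb))
        return float(np.nanmean(r_pool) - np.nanmean(r_tr))

    observed = statistic(cols_a, cols_b)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = rng.permutation(pool)
        null[i] = statistic(shuffled[: cols_a.size], shuffled[cols_a.size :])
    if two_sided:
        exceed = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        exceed = int(np.sum(null >= observed))
    p = (exceed + 1) / (n_perm + 1)
    return p, observed, null
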