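"""Trial-level data containers, readers and quality-control exclusions.

The atom of every computation in this package is the :class:`TrialMatrix`:
an ``N x T`` array of per-trial outcomes (binary or real-valued) for ``N``
participants, with per-trial metadata (form, session, trial index).  Long
(tidy) delimited text is the canonical on-disk representation; wide
participant-by-trial matrices are accepted and converted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TrialMatrix",
    "ScoreStats",
    "ExclusionConfig",
    "ExclusionReport",
    "SchemaError",
    "read_trials",
    "concat_sessions",
    "participant_scores",
    "apply_exclusions",
]

#: default mapping from semantic role to column name in delimited files
DEFAULT_SCHEMA = {
    "participant": "participant",
    "task": "task",
    "form": "form",
    "session": "session",
    "trial": "trial",
    "outcome": "outcome",
    "rt": "rt",
    "response": "response",
}


class SchemaError(ValueError):
    """Raised when a file cannot be mapped onto the expected columns."""


@dataclass
class TrialMatrix:
    """Participant-by-trial outcomes with form/session labels.

    Parameters
    ----------
    outcomes
        ``(N, T)`` float array; missing trials are NaN.
    participant_ids
        Length-``N`` identifiers, order matching rows of ``outcomes``.
    trial_meta
        Length-``T`` DataFrame with columns ``form``, ``session``,
        ``trial`` (0-based trial index within its session/form block).
    task_name
        Free-text task label.
    binary
        True when all non-missing outcomes are 0/1 (enables the
        mean/variance machinery which requires Bernoulli trials).
    rt, responses
        Optional aligned ``(N, T)`` arrays of reaction times and raw
        response codes, used only by the exclusion criteria.
    """

    outcomes: np.ndarray
    participant_ids: np.ndarray
    trial_meta: pd.DataFrame
    task_name: str = ""
    binary: bool | None = None
    rt: np.ndarray | None = None
    responses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        if self.outcomes.ndim != 2:
            raise ValueError("outcomes must be a 2-D (participants x trials) array")
        n, t = self.outcomes.shape
        if n < 1 or t < 1:
            raise ValueError("need at least one participant and one trial")
        self.participant_ids = np.asarray(self.participant_ids)
        if len(self.participant_ids) != n:
            raise ValueError("participant_ids length does not match outcome rows")
        if len(np.unique(self.participant_ids)) != n:
            raise ValueError("participant_ids must be unique")
        if not isinstance(self.trial_meta, pd.DataFrame):
            self.trial_meta = pd.DataFrame(self.trial_meta)
        for col in ("form", "session", "trial"):
            if col not in self.trial_meta.columns:
                raise ValueError(f"trial_meta missing column {col!r}")
        if len(self.trial_meta) != t:
            raise ValueError("trial_meta length does not match outcome columns")
        self.trial_meta = self.trial_meta.reset_index(drop=True)
        usable = np.isfinite(self.outcomes).sum(axis=1)
        if (usable == 0).any():
            bad = self.participant_ids[usable == 0]
            raise ValueError(f"participants with no usable trials: {list(bad)}")
        finite = self.outcomes[np.isfinite(self.outcomes)]
        is_binary = bool(np.isin(finite, (0.0, 1.0)).all())
        if self.binary is None:
            self.binary = is_binary
        elif self.binary and not is_binary:
            raise ValueError("binary=True but outcomes outside {0, 1} present")
        if self.rt is not None:
            self.rt = np.asarray(self.rt, dtype=float)
            if self.rt.shape != self.outcomes.shape:
                raise ValueError("rt matrix not aligned with outcomes")
        if self.responses is not None:
            self.responses = np.asarray(self.responses)
            if self.responses.shape != self.outcomes.shape:
                raise ValueError("responses matrix not aligned with outcomes")

    # -- basic geometry -------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_trials(self) -> int:
        return self.outcomes.shape[1]

    @property
    def sessions(self) -> list:
        """Session labels in column order of first appearance."""
        return list(pd.unique(self.trial_meta["session"]))

    def session_columns(self, label) -> np.ndarray:
        """Column indices belonging to one session."""
        cols = np.flatnonzero((self.trial_meta["session"] == label).to_numpy())
        if cols.size == 0:
            raise KeyError(f"unknown session label {label!r}; have {self.sessions}")
        return cols

    def split_sessions(self) -> dict:
        """Return ``{session label: TrialMatrix}`` restricted to each session."""
        return {s: self.select_columns(self.session_columns(s)) for s in self.sessions}

    def select_columns(self, cols: np.ndarray) -> "TrialMatrix":
        cols = np.asarray(cols, dtype=int)
        return TrialMatrix(
            outcomes=self.outcomes[:, cols],
            participant_ids=self.participant_ids,
            trial_meta=self.trial_meta.iloc[cols].reset_index(drop=True),
            task_name=self.task_name,
            binary=self.binary,
            rt=None if self.rt is None else self.rt[:, cols],
            responses=None if self.responses is None else self.responses[:, cols],
        )

    def select_participants(self, mask_or_ids) -> "TrialMatrix":
        mask = np.asarray(mask_or_ids)
        if mask.dtype != bool:
            mask = np.isin(self.participant_ids, mask)
        return TrialMatrix(
            outcomes=self.outcomes[mask],
            participant_ids=self.participant_ids[mask],
            trial_meta=self.trial_meta,
            task_name=self.task_name,
            binary=self.binary,
            rt=None if self.rt is None else self.rt[mask],
            responses=None if self.responses is None else self.responses[mask],
        )

    # -- wide / long conversion -----------------------------------------
    @classmethod
    def from_wide(
        cls,
        matrix,
        participant_ids=None,
        session: str = "1",
        form: str = "1",
        task_name: str = "",
        binary: bool | None = None,
    ) -> "TrialMatrix":
        """Build from a wide participant-by-trial array or DataFrame."""
        if isinstance(matrix, pd.DataFrame):
            if participant_ids is None:
                participant_ids = matrix.index.to_numpy()
            matrix = matrix.to_numpy(dtype=float)
        matrix = np.asarray(matrix, dtype=float)
        if participant_ids is None:
            participant_ids = np.arange(matrix.shape[0])
        t = matrix.shape[1]
        meta = pd.DataFrame(
            {"form": [form] * t, "session": [session] * t, "trial": np.arange(t)}
        )
        return cls(matrix, np.asarray(participant_ids), meta, task_name, binary)

    def to_long_frame(self) -> pd.DataFrame:
        """Long (tidy) representation; trial indices 1-based for reporting."""
        n, t = self.outcomes.shape
        frame = pd.DataFrame(
            {
                "participant": np.repeat(self.participant_ids, t),
                "task": self.task_name,
                "form": np.tile(self.trial_meta["form"].to_numpy(), n),
                "session": np.tile(self.trial_meta["session"].to_numpy(), n),
                "trial": np.tile(self.trial_meta["trial"].to_numpy() + 1, n),
                "outcome": self.outcomes.ravel(),
            }
        )
        if self.rt is not None:
            frame["rt"] = self.rt.ravel()
        if self.responses is not None:
            frame["response"] = self.responses.ravel()
        return frame.dropna(subset=["outcome"]).reset_index(drop=True)

    def write(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def concat_sessions(matrices: dict | list) -> TrialMatrix:
    """Concatenate per-session matrices (shared participants) column-wise.

    Accepts a ``{session label: TrialMatrix}`` mapping or a list (labels
    become ``"1"``, ``"2"``, ...).  Only participants present in every
    session are retained, in the order of the first matrix.
    """
    if isinstance(matrices, dict):
        items = list(matrices.items())
    else:
        items = [(str(i + 1), m) for i, m in enumerate(matrices)]
    if not items:
        raise ValueError("nothing to concatenate")
    shared = items[0][1].participant_ids
    for _, m in items[1:]:
        shared = shared[np.isin(shared, m.participant_ids)]
    if shared.size < 1:
        raise ValueError("no shared participants across sessions")
    blocks, metas = [], []
    for label, m in items:
        order = {p: i for i, p in enumerate(m.participant_ids)}
        rows = np.array([order[p] for p in shared])
        blocks.append(m.outcomes[rows])
        meta = m.trial_meta.copy()
        meta["session"] = label
        metas.append(meta)
    return TrialMatrix(
        outcomes=np.hstack(blocks),
        participant_ids=shared,
        trial_meta=pd.concat(metas, ignore_index=True),
        task_name=items[0][1].task_name,
    )


# ---------------------------------------------------------------------------
# reading delimited text
# ---------------------------------------------------------------------------

def read_trials(
    path,
    schema: dict | None = None,
    binary: bool | None = None,
    delimiter: str | None = None,
) -> TrialMatrix:
    """Read long-format trial-level data from CSV/TSV.

    ``schema`` maps the semantic roles (``participant``, ``trial``,
    ``outcome``, optionally ``form``, ``session``, ``rt``, ``response``,
    ``task``) onto the file's column names; unmapped optional roles fall
    back to the defaults or to a single form/session.  The delimiter is
    sniffed when not given.  Columns are ordered by
    ``(session, form, trial)``; ``binary`` is auto-detected unless
    overridden.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    for role in ("participant", "trial", "outcome"):
        if schema[role] not in df.columns:
            raise SchemaError(
                f"required column for role {role!r} ({schema[role]!r}) not found; "
                f"file has {list(df.columns)}"
            )
    out_col = schema["outcome"]
    outcome = pd.to_numeric(df[out_col], errors="coerce")
    bad = outcome.isna() & df[out_col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"non-numeric outcome {df[out_col].iloc[row]!r} at data row {row + 1}"
        )
    work = pd.DataFrame(
        {
            "participant": df[schema["participant"]],
            "trial": df[schema["trial"]],
            "outcome": outcome,
        }
    )
    work["form"] = df[schema["form"]].astype(str) if schema["form"] in df.columns else "1"
    work["session"] = (
        df[schema["session"]].astype(str) if schema["session"] in df.columns else "1"
    )
    for role in ("rt", "response"):
        if schema[role] in df.columns:
            work[role] = df[schema[role]]
    task_name = (
        str(df[schema["task"]].iloc[0]) if schema["task"] in df.columns else ""
    )

    key = ["participant", "session", "form", "trial"]
    dup = work.duplicated(subset=key, keep=False)
    if dup.any():
        first = work.loc[dup, key].iloc[0].to_dict()
        raise ValueError(f"duplicate (participant, session, form, trial) key: {first}")

    col_meta = (
        work[["session", "form", "trial"]]
        .drop_duplicates()
        .sort_values(["session", "form", "trial"], kind="stable")
        .reset_index(drop=True)
    )
    col_key = list(col_meta.itertuples(index=False, name=None))
    col_index = {k: i for i, k in enumerate(col_key)}
    participants = pd.unique(work["participant"])
    n, t = len(participants), len(col_meta)
    row_index = {p: i for i, p in enumerate(participants)}

    outcomes = np.full((n, t), np.nan)
    rts = np.full((n, t), np.nan) if "rt" in work.columns else None
    responses = np.full((n, t), np.nan, dtype=object) if "response" in work.columns else None
    rows = work["participant"].map(row_index).to_numpy()
    cols = np.array(
        [col_index[k] for k in zip(work["session"], work["form"], work["trial"])]
    )
    outcomes[rows, cols] = work["outcome"].to_numpy()
    if rts is not None:
        rts[rows, cols] = pd.to_numeric(work["rt"], errors="coerce").to_numpy()
    if responses is not None:
        responses[rows, cols] = work["response"].to_numpy()

    meta = pd.DataFrame(
        {
            "form": col_meta["form"].to_numpy(),
            "session": col_meta["session"].to_numpy(),
            "trial": np.arange(t),  # 0-based internal index in column order
        }
    )
    return TrialMatrix(
        outcomes=outcomes,
        participant_ids=participants,
        trial_meta=meta,
        task_name=task_name,
        binary=binary,
        rt=rts,
        responses=responses,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreStats:
    """Summary statistics of per-participant scores.

    ``var_z`` is the unbiased (n-1 denominator) sample variance across
    participants; ``n_trials_per_participant`` is the number of trial
    columns each score averages over (the ``T`` of the finite-sampling
    correction).
    """

    mean_z: float
    var_z: float
    n_participants: int
    n_trials_per_participant: int

    def __post_init__(self):
        if self.var_z < 0:
            raise ValueError("variance cannot be negative")


def participant_scores(
    data: TrialMatrix,
    columns: np.ndarray | None = None,
    min_trials: int = 1,
):
    """Score each participant as the mean of their non-missing outcomes.

    Returns ``(scores, stats)`` where ``scores`` is a Series indexed by
    participant id (participants with fewer than ``min_trials`` usable
    trials in the selected columns are dropped with a warning) and
    ``stats`` is a :class:`ScoreStats` over the retained participants.
    """
    if columns is None:
        sub = data.outcomes
        t_used = data.n_trials
    else:
        columns = np.asarray(columns, dtype=int)
        if columns.size == 0:
            raise ValueError("empty column subset")
        sub = data.outcomes[:, columns]
        t_used = columns.size
    counts = np.isfinite(sub).sum(axis=1)
    keep = counts >= max(1, min_trials)
    if not keep.any():
        raise ValueError("no participant has enough usable trials in the subset")
    if not keep.all():
        dropped = data.participant_ids[~keep]
        warnings.warn(
            f"dropping {len(dropped)} participant(s) with <{min_trials} usable "
            f"trials: {list(dropped)[:5]}{'...' if len(dropped) > 5 else ''}"
        )
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(sub[keep], axis=1)
    scores = pd.Series(vals, index=pd.Index(data.participant_ids[keep], name="participant"))
    var = float(vals.var(ddof=1)) if keep.sum() > 1 else 0.0
    stats = ScoreStats(
        mean_z=float(vals.mean()),
        var_z=var,
        n_participants=int(keep.sum()),
        n_trials_per_participant=int(t_used),
    )
    return scores, stats


# ---------------------------------------------------------------------------
# quality-control exclusions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionConfig:
    """Thresholds for the generic behavioral exclusion criteria.

    A participant is excluded when at least two of the following fire,
    all at ``k_sd`` group standard deviations:

    a. mean reaction time faster than the group mean of mean RTs;
    b. SD of reaction times below the group mean of RT SDs;
    c. mean same-response run length above the group mean.

    Participants whose accuracy is no more than ``accuracy_guard_sd`` SD
    below the group mean accuracy are retained regardless.  With
    ``strict_rt_sd`` the RT-variability criterion (b) alone excludes,
    regardless of accuracy (the bot-detection variant used for
    recognition-memory tasks, where flat RT profiles indicate scripted
    responding).
    """

    k_sd: float = 2.0
    accuracy_guard_sd: float = 0.5
    strict_rt_sd: bool = False


@dataclass
class ExclusionReport:
    flags: pd.DataFrame
    excluded: list
    config: ExclusionConfig

    def to_json(self) -> str:
        return json.dumps(
            {
                "excluded": [str(p) for p in self.excluded],
                "n_excluded": len(self.excluded),
                "config": {
                    "k_sd": self.config.k_sd,
                    "accuracy_guard_sd": self.config.accuracy_guard_sd,
                    "strict_rt_sd": self.config.strict_rt_sd,
                },
            },
            indent=2,
        )

    def write(self, csv_path, json_path=None) -> None:
        self.flags.to_csv(csv_path)
        if json_path is not None:
            with open(json_path, "w") as fh:
                fh.write(self.to_json())


def _mean_run_length(row: np.ndarray) -> float:
    """Mean length of runs of identical consecutive non-missing responses."""
    vals = row[~pd.isna(row)]
    if vals.size == 0:
        return np.nan
    change = np.flatnonzero(vals[1:] != vals[:-1])
    run_lengths = np.diff(np.concatenate(([0], change + 1, [vals.size])))
    run_lengths = run_lengths[run_lengths > 0]
    return float(run_lengths.mean())


def apply_exclusions(
    data: TrialMatrix,
    rts: np.ndarray | None = None,
    config: ExclusionConfig | None = None,
) -> ExclusionReport:
    """Flag and exclude non-compliant participants.

    Group statistics are computed once over all participants (not
    iteratively re-estimated after each exclusion).  Participants with
    no recorded RTs skip the two RT criteria with a warning.
    """
    config = config or ExclusionConfig()
    if data.n_participants < 3:
        raise ValueError("need at least 3 participants for group statistics")
    if rts is None:
        rts = data.rt
    n = data.n_participants
    k = config.k_sd

    if rts is not None:
        rts = np.asarray(rts, dtype=float)
        if rts.shape != data.outcomes.shape:
            raise ValueError("RT matrix not aligned with outcomes")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_rt = np.nanmean(rts, axis=1)
            sd_rt = np.nanstd(rts, axis=1, ddof=1)
        missing_rt = ~np.isfinite(mean_rt) | ~np.isfinite(sd_rt)
        if missing_rt.any():
            warnings.warn(
                f"{int(missing_rt.sum())} participant(s) lack RTs; "
                "RT criteria skipped for them"
            )
    else:
        mean_rt = np.full(n, np.nan)
        sd_rt = np.full(n, np.nan)
        missing_rt = np.ones(n, dtype=bool)
        warnings.warn("no RT data supplied; RT criteria skipped for everyone")

    run_source = data.responses if data.responses is not None else data.outcomes
    run_len = np.array([_mean_run_length(row) for row in run_source])
    accuracy = np.nanmean(data.outcomes, axis=1)

    def group(x):
        ok = np.isfinite(x)
        if ok.sum() < 2:
            return np.nan, np.nan
        return float(np.mean(x[ok])), float(np.std(x[ok], ddof=1))

    g_mean_rt, g_sd_mean_rt = group(mean_rt)
    g_mean_sdrt, g_sd_sdrt = group(sd_rt)
    g_run, g_sd_run = group(run_len)
    g_acc, g_sd_acc = group(accuracy)

    crit_a = np.where(missing_rt, False, mean_rt < g_mean_rt - k * g_sd_mean_rt)
    crit_b = np.where(missing_rt, False, sd_rt < g_mean_sdrt - k * g_sd_sdrt)
    crit_c = (
        np.zeros(n, dtype=bool)
        if not np.isfinite(g_sd_run)
        else run_len > g_run + k * g_sd_run
    )
    n_fired = crit_a.astype(int) + crit_b.astype(int) + crit_c.astype(int)
    guard = (
        accuracy > g_acc - config.accuracy_guard_sd * g_sd_acc
        if np.isfinite(g_sd_acc)
        else np.ones(n, dtype=bool)
    )
    excluded = (n_fired >= 2) & ~guard
    if config.strict_rt_sd:
        excluded = excluded | crit_b

    flags = pd.DataFrame(
        {
            "fast_mean_rt": crit_a,
            "low_rt_sd": crit_b,
            "long_response_runs": crit_c,
            "n_criteria": n_fired,
            "accuracy": accuracy,
            "accuracy_guard": guard,
            "excluded": excluded,
        },
        index=pd.Index(data.participant_ids, name="participant"),
    )
    excluded_ids = list(data.participant_ids[excluded])
    for pid in excluded_ids:
        row = flags.loc[pid]
        fired = [
            c
            for c in ("fast_mean_rt", "low_rt_sd", "long_response_runs")
            if row[c]
        ]
        logger.info("excluding %s (criteria: %s)", pid, ", ".join(fired))
    return ExclusionReport(flags=flags, excluded=excluded_ids, config=config)
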