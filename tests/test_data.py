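"""Readers, scoring, and quality-control exclusions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relcurve import (
    ExclusionConfig,
    TrialMatrix,
    apply_exclusions,
    participant_scores,
    read_trials,
)
from relcurve.data import SchemaError


class TestReadTrials:
    def test_single_participant_binary(self, trials_csv):
        path = trials_csv([("p1", "1", t, o) for t, o in enumerate([1, 0, 1])])
        m = read_trials(path)
        assert m.n_participants == 1 and m.n_trials == 3
        assert m.binary
        np.testing.assert_array_equal(m.outcomes, [[1.0, 0.0, 1.0]])

    def test_non_binary_detection(self, trials_csv):
        path = trials_csv([("p1", "1", 0, 0.5), ("p1", "1", 1, 1.0)])
        assert not read_trials(path).binary

    def test_duplicate_key_rejected(self, trials_csv):
        path = trials_csv([("p1", "1", 0, 1), ("p1", "1", 0, 0)])
        with pytest.raises(ValueError, match="duplicate"):
            read_trials(path)

    def test_schema_mapping_and_missing_column(self, trials_csv):
        path = trials_csv(
            [("p1", "a", 0, 1), ("p1", "a", 1, 0)],
            columns=("subj", "sess", "item", "correct"),
        )
        m = read_trials(
            path,
            schema={"participant": "subj", "session": "sess", "trial": "item", "outcome": "correct"},
        )
        assert m.sessions == ["a"]
        with pytest.raises(SchemaError, match="not found"):
            read_trials(path)

    def test_non_numeric_outcome_names_row(self, trials_csv):
        path = trials_csv([("p1", "1", 0, 1), ("p1", "1", 1, "oops")])
        with pytest.raises(ValueError, match="oops"):
            read_trials(path)

    def test_long_roundtrip(self, beta_binomial_factory, tmp_path):
        m = beta_binomial_factory(2, 2, 10, 20, seed=5)
        path = tmp_path / "roundtrip.csv"
        m.write(path)
        back = read_trials(path)
        np.testing.assert_array_equal(back.outcomes, m.outcomes)


class TestParticipantScores:
    def test_extreme_rows(self):
        m = TrialMatrix.from_wide(np.array([[1, 1, 1, 1], [0, 0, 0, 0]], float), binary=True)
        scores, stats = participant_scores(m)
        np.testing.assert_array_equal(scores.to_numpy(), [1.0, 0.0])
        assert stats.mean_z == 0.5

    def test_missing_trials_ignored(self):
        m = TrialMatrix.from_wide(np.array([[1, 0, np.nan, 1], [0, 1, 0, 0]]))
        scores, _ = participant_scores(m)
        assert scores.iloc[0] == pytest.approx(2 / 3)

    def test_law_of_total_variance(self, rng):
        # Var(Z) = Var(P) + E[p(1-p)]/T for Beta(2,2)-binomial scores
        n, t = 2000, 250
        p = rng.beta(2, 2, n)
        m = TrialMatrix.from_wide((rng.random((n, t)) < p[:, None]).astype(float))
        _, stats = participant_scores(m)
        expected = 0.05 + 0.2 / t
        assert stats.mean_z == pytest.approx(0.5, abs=0.02)
        assert stats.var_z == pytest.approx(expected, rel=0.10)

    def test_empty_subset_rejected(self, deterministic_matrix):
        with pytest.raises(ValueError, match="empty"):
            participant_scores(deterministic_matrix, columns=np.array([], dtype=int))

    def test_column_permutation_equivariance(self, beta_binomial_factory):
        m = beta_binomial_factory(3, 3, 20, 30, seed=2)
        perm = np.random.default_rng(0).permutation(30)
        s1, _ = participant_scores(m)
        s2, _ = participant_scores(m.select_columns(perm))
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.integers(4, 12).flatmap(
            lambda t: st.lists(
                st.lists(st.integers(0, 1), min_size=t, max_size=t),
                min_size=2,
                max_size=15,
            )
        )
    )
    def test_binary_variance_bound(self, data):
        """Unbiased score variance obeys the n/(n-1)-adjusted Bhatia-Davis bound."""
        m = TrialMatrix.from_wide(np.array(data, float), binary=True)
        _, stats = participant_scores(m)
        n = stats.n_participants
        bound = stats.mean_z * (1 - stats.mean_z) * n / (n - 1)
        assert 0 <= stats.var_z <= bound + 1e-12


def _compliant_cohort(rng, n=30, t=60):
    p = rng.beta(4, 4, n)
    outcomes = (rng.random((n, t)) < p[:, None]).astype(float)
    rt = rng.lognormal(mean=0.0, sigma=0.25, size=(n, t)) + 0.3
    responses = (rng.random((n, t)) < 0.5).astype(float)
    return outcomes, rt, responses


class TestExclusions:
    def test_homogeneous_cohort_keeps_everyone(self, rng):
        outcomes, rt, responses = _compliant_cohort(rng)
        m = TrialMatrix.from_wide(outcomes, binary=True)
        m.rt, m.responses = rt, responses
        report = apply_exclusions(m)
        assert report.excluded == []

    def _with_bot(self, rng, bot_accuracy):
        outcomes, rt, responses = _compliant_cohort(rng)
        # constant single-key responder with near-zero RT variability
        responses[0] = 1.0
        rt[0] = 1.0 + rng.normal(0, 1e-4, rt.shape[1])
        outcomes[0] = (np.arange(outcomes.shape[1]) % (1 / bot_accuracy) < 1).astype(float) \
            if bot_accuracy < 1 else 1.0
        m = TrialMatrix.from_wide(outcomes, binary=True)
        m.rt, m.responses = rt, responses
        return m

    def test_flat_responder_fires_rt_sd_and_run_length(self, rng):
        m = self._with_bot(rng, bot_accuracy=0.25)
        report = apply_exclusions(m)
        row = report.flags.iloc[0]
        assert row["low_rt_sd"] and row["long_response_runs"]
        assert report.excluded == [m.participant_ids[0]]

    def test_accuracy_guard_vs_strict_rt_rule(self, rng):
        outcomes, rt, responses = _compliant_cohort(rng)
        responses[0] = 1.0
        rt[0] = 1.0 + rng.normal(0, 1e-4, rt.shape[1])
        outcomes[0] = outcomes[1:].mean(0).round()  # accuracy at the group mean
        m = TrialMatrix.from_wide(outcomes, binary=True)
        m.rt, m.responses = rt, responses
        default = apply_exclusions(m)
        assert m.participant_ids[0] not in default.excluded
        strict = apply_exclusions(m, config=ExclusionConfig(strict_rt_sd=True))
        assert m.participant_ids[0] in strict.excluded

    def test_determinism_and_small_group_error(self, rng):
        m = self._with_bot(rng, bot_accuracy=0.25)
        r1 = apply_exclusions(m)
        r2 = apply_exclusions(m)
        pd.testing.assert_frame_equal(r1.flags, r2.flags)
        tiny = TrialMatrix.from_wide(np.eye(2), binary=True)
        with pytest.raises(ValueError, match="3 participants"):
            apply_exclusions(tiny)
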