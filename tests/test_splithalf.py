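"""Permutation split-halves and test-retest curve estimation."""

import numpy as np
import pytest

from relcurve import (
    SyntheticSpec,
    averaged_testretest,
    concat_sessions,
    curve_difference_test,
    random_null_data,
    rl_curve,
    rl_point,
    simulate_sessions,
    testretest_curve as _testretest_curve,
)
from relcurve.data import TrialMatrix
from relcurve.splithalf import ConstantScoreError, _column_samples, auto_grid


class TestRLPoint:
    def test_deterministic_participants_give_perfect_reliability(
        self, deterministic_matrix, rng
    ):
        mean, sd, _ = rl_point(deterministic_matrix, L=10, n_perm=50, rng=rng)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_identical_participants_error(self, rng):
        m = TrialMatrix.from_wide(np.ones((5, 20)), binary=True)
        with pytest.raises(ConstantScoreError):
            rl_point(m, L=5, n_perm=20, rng=rng)

    def test_random_data_noise_floor(self, rng):
        m = random_null_data(100, 250, rng=rng)
        mean, _, _ = rl_point(m, L=30, n_perm=300, rng=rng)
        assert -0.1 < mean < 0.1

    def test_halves_are_disjoint(self, rng):
        a, b = _column_samples(rng, np.arange(40), (15, 15), 200)
        for i in range(200):
            assert not set(a[i]) & set(b[i])
            assert len(set(a[i])) == 15 and len(set(b[i])) == 15

    def test_l_bounds(self, deterministic_matrix, rng):
        with pytest.raises(ValueError):
            rl_point(deterministic_matrix, L=21, n_perm=10, rng=rng)


class TestRLCurve:
    def test_auto_grid_shape(self):
        g = auto_grid(125)
        assert g[0] == 2 and g[-1] == 125
        assert len(g) >= 10 and np.all(np.diff(g) > 0)
        assert list(auto_grid(5)) == [2, 3, 4, 5]

    def test_grid_out_of_range_listed(self, deterministic_matrix, rng):
        with pytest.raises(ValueError, match="21"):
            rl_curve(deterministic_matrix, [5, 21], n_perm=10, rng=rng)

    def test_deterministic_curve_is_one(self, deterministic_matrix, rng):
        c = rl_curve(deterministic_matrix, [2, 5, 10], n_perm=50, rng=rng)
        np.testing.assert_allclose(c.R_mean, 1.0)

    def test_beta_binomial_curve_tracks_hyperbola(self, beta_binomial_factory, rng):
        # Beta(2,2)-binomial: expected R(L) = L/(L+4)
        data = beta_binomial_factory(2, 2, 200, 250, seed=11)
        c = rl_curve(data, "auto", n_perm=500, rng=rng)
        expected = c.L_values / (c.L_values + 4.0)
        # cohort-level wobble adds to the resampling SD; 2 sd + a small floor
        assert np.all(np.abs(c.R_mean - expected) <= 2 * c.R_sd + 0.03)

    def test_monotone_in_expectation(self, beta_binomial_factory, rng):
        data = beta_binomial_factory(3, 3, 150, 200, seed=3)
        c = rl_curve(data, "auto", n_perm=400, rng=rng)
        dips = np.diff(c.R_mean)
        slack = 2 * np.maximum(c.R_sd[1:], c.R_sd[:-1])
        assert np.all(dips >= -slack)

    def test_cronbach_alpha_equivalence(self, beta_binomial_factory, rng):
        """Spearman-Brown-corrected split-half at L=T/2 matches alpha on all T items."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        data = beta_binomial_factory(2, 2, 200, 100, seed=7)
        mean, _, _ = rl_point(data, L=50, n_perm=500, rng=rng)
        corrected = 2 * mean / (1 + mean)
        alpha = pingouin.cronbach_alpha(pd.DataFrame(data.outcomes))[0]
        assert corrected == pytest.approx(alpha, abs=0.02)

    def test_null_mean_curve_near_zero(self, rng):
        """Averaging whole random-data curves over replicates stays within [-0.01, 0.02]."""
        curves = []
        for _ in range(30):
            d = random_null_data(100, 250, rng=rng)
            curves.append(rl_curve(d, "auto", n_perm=300, rng=rng).R_mean)
        grand = float(np.mean(curves))
        assert -0.01 <= grand <= 0.02


def _two_sessions(noise_sd, seed, n=150, t=120):
    spec = SyntheticSpec(2, 2, n, t, session_noise_sd=noise_sd, seed=seed)
    return concat_sessions(simulate_sessions(spec, 2, spec.rng()))


class TestTestRetest:
    def test_identical_sessions_deterministic(self, rng):
        p = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        block = np.repeat(p[:, None], 20, axis=1)
        data = concat_sessions([TrialMatrix.from_wide(block), TrialMatrix.from_wide(block)])
        c = _testretest_curve(data, "1", "2", [2, 5, 10], n_perm=30, rng=rng)
        np.testing.assert_allclose(c.R_mean, 1.0)
        assert c.mode == "testretest"

    def test_unknown_session_label(self, rng):
        data = _two_sessions(0.0, seed=1)
        with pytest.raises(KeyError):
            _testretest_curve(data, "1", "zzz", [5], n_perm=10, rng=rng)

    def test_no_session_effect_matches_pooled(self, rng):
        data = _two_sessions(0.0, seed=2)
        L = 40
        tr_m, tr_sd, _ = __import__("relcurve").splithalf.testretest_point(
            data, "1", "2", L, n_perm=400, rng=rng
        )
        pool_m, pool_sd, _ = rl_point(data, L, n_perm=400, rng=rng)
        assert abs(tr_m - pool_m) < 3 * max(tr_sd, pool_sd)

    def test_session_noise_lowers_testretest(self):
        gaps = []
        for seed in range(3):
            data = _two_sessions(0.15, seed=seed)
            gen = np.random.default_rng(seed)
            L = 40
            from relcurve.splithalf import testretest_point

            tr_m, _, _ = testretest_point(data, "1", "2", L, n_perm=300, rng=gen)
            pool_m, _, _ = rl_point(data, L, n_perm=300, rng=gen)
            gaps.append(pool_m - tr_m)
        assert np.mean(gaps) > 0.02


class TestAveragedTestRetest:
    def _days(self, noise_sd, n_days, seed, n=120, t=80):
        spec = SyntheticSpec(2, 2, n, t, session_noise_sd=noise_sd, seed=seed)
        mats = simulate_sessions(spec, n_days, spec.rng())
        return {str(i + 1): m for i, m in enumerate(mats)}

    def test_singleton_groups_reduce_to_testretest(self, rng):
        days = self._days(0.1, 2, seed=4)
        data = concat_sessions(days)
        L = [10, 20, 40]
        avg = averaged_testretest(days, ["1"], ["2"], L, n_perm=400, rng=np.random.default_rng(0))
        tr = _testretest_curve(data, "1", "2", L, n_perm=400, rng=np.random.default_rng(0))
        np.testing.assert_allclose(avg.R_mean, tr.R_mean, atol=3 * np.max(tr.R_sd))

    def test_multi_day_averaging_raises_reliability(self):
        days = self._days(0.15, 6, seed=5)
        one = averaged_testretest(days, ["1"], ["4"], [30], n_perm=400, rng=np.random.default_rng(1))
        three = averaged_testretest(
            days, ["1", "2", "3"], ["4", "5", "6"], [30], n_perm=400, rng=np.random.default_rng(1)
        )
        assert three.R_mean[0] > one.R_mean[0]

    def test_zero_noise_grouping_no_effect_at_matched_total(self):
        # without session noise, 2 days x 15 trials carries the same
        # information as 1 day x 30 trials; grouping itself adds nothing
        days = self._days(0.0, 4, seed=6)
        one = averaged_testretest(days, ["1"], ["2"], [30], n_perm=400, rng=np.random.default_rng(2))
        two = averaged_testretest(
            days, ["1", "3"], ["2", "4"], [15], n_perm=400, rng=np.random.default_rng(2)
        )
        assert abs(two.R_mean[0] - one.R_mean[0]) < 3 * max(one.R_sd[0], two.R_sd[0])

    def test_overlapping_groups_rejected(self):
        days = self._days(0.0, 2, seed=7)
        with pytest.raises(ValueError, match="disjoint"):
            averaged_testretest(days, ["1"], ["1"], [5], n_perm=10)


class TestCurveDifferenceTest:
    def test_strong_session_shift_detected(self):
        data = _two_sessions(0.25, seed=8, n=120, t=100)
        p, obs, null = curve_difference_test(
            data, "1", "2", L=40, n_perm=199, rng=np.random.default_rng(3), n_inner=60
        )
        assert p <= 0.01
        assert obs > np.quantile(null, 0.99)

    def test_null_p_values_not_concentrated(self):
        ps = []
        for seed in range(12):
            data = _two_sessions(0.0, seed=100 + seed, n=60, t=60)
            p, _, _ = curve_difference_test(
                data, "1", "2", L=20, n_perm=49, rng=np.random.default_rng(seed), n_inner=40
            )
            ps.append(p)
        assert 0.25 < np.mean(ps) < 0.75

    def test_l_bound(self):
        data = _two_sessions(0.0, seed=9, t=40)
        with pytest.raises(ValueError):
            curve_difference_test(data, "1", "2", L=41, n_perm=10)
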