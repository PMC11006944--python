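"""Behavioral statistics: conditioning, rank tests, FDR, robust means."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import ctree_rt as crt


class TestSplitEpochs:
    def test_protocol_rest_positions(self):
        assert crt.split_epochs(1000, (334, 668)) == [(1, 334), (335, 668), (669, 1000)]

    def test_no_boundaries(self):
        assert crt.split_epochs(10, ()) == [(1, 10)]

    @pytest.mark.parametrize("bad", [(10,), (0,), (5, 5), (7, 3)])
    def test_invalid_boundaries(self, bad):
        with pytest.raises(ValueError):
            crt.split_epochs(10, bad)


class TestTransitionCounts:
    def test_correctly_predicted_zero_to_two(self, worked_session):
        s = worked_session  # Y correct except trials 2 and 5
        s.predictions[1] = 2  # make trial 2 correct for this case
        c = crt.transition_counts(s.kicks, s.predictions, (0,), 2)
        assert (c.n_correct, c.n_incorrect) == (2, 0)

    def test_incorrect_zero_to_one(self, worked_session):
        s = worked_session  # trial 5: X_5 = 1 but Y_5 = 2
        c = crt.transition_counts(s.kicks, s.predictions, (0,), 1)
        assert (c.n_correct, c.n_incorrect) == (0, 1)

    def test_absent_context(self, worked_session):
        c = crt.transition_counts(worked_session.kicks, worked_session.predictions, (2, 2), 0)
        assert (c.n_correct, c.n_incorrect) == (0, 0)

    def test_index_permutation_invariance(self, worked_session):
        c = crt.transition_counts(worked_session.kicks, worked_session.predictions, (0,), 2)
        # the index depends on counts only, so occurrence order cannot matter
        assert crt.correct_transition_index(c) == c.n_correct / (c.n_correct + c.n_incorrect)


class TestCorrectTransitionIndex:
    def test_values(self):
        mk = lambda nc, ni: crt.TransitionCounts((0,), 2, np.arange(nc), np.arange(ni))
        assert crt.correct_transition_index(mk(7, 3)) == pytest.approx(0.7)
        assert crt.correct_transition_index(mk(0, 5)) == 0.0
        assert crt.correct_transition_index(mk(2, 0)) == 1.0
        with pytest.raises(ZeroDivisionError):
            crt.correct_transition_index(mk(0, 0))


class TestConditioning:
    def test_one_step_forward_success(self, worked_session):
        s = worked_session
        s.predictions[1] = 2  # trial 2 correct
        cond = crt.condition_rt_on_last_zero_outcome(
            s.kicks, s.predictions, s.response_times, (2,)
        )
        assert 3.0 in cond.success  # T_3 follows context 2 ending at trial 2

    def test_two_step_forward_failure(self, worked_session):
        s = worked_session  # trial 5 wrong
        cond = crt.condition_rt_on_last_zero_outcome(
            s.kicks, s.predictions, s.response_times, (0, 1)
        )
        assert 6.0 in cond.failure  # occurrence of 01 ends at trial 5, m* = 4

    def test_context_zero_uses_previous_triplet(self, worked_session):
        s = worked_session
        s.predictions[1] = 1  # trial 2 (prediction after the first 0) wrong
        cond = crt.condition_rt_on_last_zero_outcome(
            s.kicks, s.predictions, s.response_times, (0,)
        )
        # occurrence of 0 ending at trial 4 conditions on Y_2 vs X_2
        assert 5.0 in cond.failure
        # first occurrence (trial 1) has no preceding 0-transition: discarded
        assert cond.n_discarded == 1

    def test_partition_of_occurrences(self, generating_model):
        k = crt.generate_kicks(generating_model, 2000, seed=61)
        y = crt.generate_predictions(k, crt.BehaviorModel.default(), generating_model.tree, seed=62)
        t = crt.generate_response_times(k, y, crt.RTModel.default(), seed=63)
        from ctree_rt.estimator import occurrence_ends

        for w in [(0,), (2,), (0, 1), (1, 1), (2, 1)]:
            cond = crt.condition_rt_on_last_zero_outcome(k, y, t, w)
            ends = occurrence_ends(k, w)
            counted = int(np.sum(ends + 1 < len(k)))
            assert len(cond.success) + len(cond.failure) + cond.n_discarded == counted

    def test_anchor_never_occurs(self):
        cond = crt.condition_rt_on_last_zero_outcome([1, 2, 1], [1, 1, 1], [0.5] * 3, (1,))
        assert len(cond.success) == len(cond.failure) == 0


class TestTrimmedMean:
    def test_drops_floor_fraction_from_each_tail(self):
        assert crt.trimmed_mean([1, 2, 3, 4, 100], 0.2) == pytest.approx(3.0)

    def test_zero_trim_is_arithmetic_mean(self):
        x = [0.3, 1.2, 5.0]
        assert crt.trimmed_mean(x, 0.0) == pytest.approx(np.mean(x))

    def test_constant_sample(self):
        assert crt.trimmed_mean([5, 5, 5, 5], 0.25) == 5.0

    def test_validation(self):
        with pytest.raises(ValueError):
            crt.trimmed_mean([], 0.2)
        with pytest.raises(ValueError):
            crt.trimmed_mean([1.0], 0.5)

    @given(st.lists(st.floats(0.1, 100), min_size=3, max_size=30), st.floats(0, 0.45))
    def test_matches_sort_drop_average_and_stays_in_range(self, xs, trim):
        cut = int(trim * len(xs))
        expected = float(np.mean(sorted(xs)[cut: len(xs) - cut]))
        got = crt.trimmed_mean(xs, trim)
        assert got == pytest.approx(expected)
        assert min(xs) - 1e-9 <= got <= max(xs) + 1e-9

    def test_approaches_median_on_odd_samples(self):
        x = [1.0, 2.0, 7.0, 11.0, 100.0]
        assert crt.trimmed_mean(x, 0.49) == np.median(x)


def _exact_signed_rank_oracle(diffs):
    """Brute-force sign-flip enumeration (midranks under ties)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    sums = [sum(c) for r in [ranks] for c in itertools.chain.from_iterable(
        itertools.combinations(r, k) for k in range(len(r) + 1))]
    sums = np.array(sums)
    p_ge = np.mean(sums >= t_obs - 1e-9)
    p_le = np.mean(sums <= t_obs + 1e-9)
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxonSignedRank:
    def test_antisymmetric_differences(self):
        res = crt.wilcoxon_signed_rank([1.5, -1.5, 2.0, -2.0], method="approx")
        assert res.z == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_six_positive_differences_exact(self):
        res = crt.wilcoxon_signed_rank([1, 2, 3, 4, 5, 6], method="exact")
        assert res.statistic == 21
        assert res.p_value == pytest.approx(0.03125)

    def test_zero_differences_dropped(self):
        a = crt.wilcoxon_signed_rank([0.0, 1.0, 2.0, -0.5], method="exact")
        b = crt.wilcoxon_signed_rank([1.0, 2.0, -0.5], method="exact")
        assert a.p_value == b.p_value
        with pytest.raises(ValueError, match="zero"):
            crt.wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(-4, 5, size=rng.integers(3, 10)).astype(float)
        if np.all(d == 0):
            d[0] = 1.0
        res = crt.wilcoxon_signed_rank(d, method="exact")
        assert res.p_value == pytest.approx(_exact_signed_rank_oracle(d))

    def test_approx_agrees_with_scipy(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 1.0, size=40)
        res = crt.wilcoxon_signed_rank(d, method="approx")
        ref = sps.wilcoxon(d, correction=False, method="approx", alternative="two-sided")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        assert abs(res.z) == pytest.approx(abs(ref.zstatistic), rel=1e-9)

    def test_sign_follows_direction(self):
        up = crt.wilcoxon_signed_rank(np.arange(1, 30.0), method="approx")
        down = crt.wilcoxon_signed_rank(-np.arange(1, 30.0), method="approx")
        assert up.z > 0 > down.z


class TestBenjaminiHochberg:
    def test_step_up_worked_example(self):
        res = crt.benjamini_hochberg([0.01, 0.02, 0.2], q=0.05)
        assert res.k == 2
        np.testing.assert_array_equal(res.rejected, [True, True, False])

    def test_single_p_equals_naive_threshold(self):
        assert crt.benjamini_hochberg([0.04], q=0.05).rejected[0]
        assert not crt.benjamini_hochberg([0.06], q=0.05).rejected[0]

    def test_nothing_rejected(self):
        res = crt.benjamini_hochberg([0.9, 0.95], q=0.05)
        assert res.k == 0 and not res.rejected.any()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 20))
        res = crt.benjamini_hochberg(p, q=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(res.rejected, ref)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=15), st.integers(1, 8))
    def test_rejections_monotone_in_q(self, ps, tens):
        q1, q2 = tens / 20, min(0.49, tens / 20 + 0.1)
        r1 = crt.benjamini_hochberg(ps, q1).rejected
        r2 = crt.benjamini_hochberg(ps, q2).rejected
        assert np.all(r2 | ~r1)  # everything rejected at q1 stays rejected at q2

    def test_validation(self):
        with pytest.raises(ValueError):
            crt.benjamini_hochberg([1.5], 0.05)
        with pytest.raises(ValueError):
            crt.benjamini_hochberg([0.5], 0.0)


def _kw_oracle(groups):
    """Tie-corrected Kruskal-Wallis H from the defining rank formula."""
    all_x = np.concatenate(groups)
    ranks = sps.rankdata(all_x)
    n = len(all_x)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx: idx + len(g)]
        idx += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_x, return_counts=True)
    correction = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


class TestKruskalWallis:
    def test_matches_rank_formula_on_disjoint_blocks(self):
        groups = [np.arange(10.0), np.arange(10.0, 20), np.arange(20.0, 30)]
        res = crt.kruskal_wallis_by_group({i: g for i, g in enumerate(groups)})
        assert res.statistic == pytest.approx(_kw_oracle(groups))
        assert res.df == 2

    def test_identical_constants_guarded(self):
        res = crt.kruskal_wallis_by_group({0: [3.0, 3.0], 1: [3.0, 3.0, 3.0]})
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(2024)
        ps = []
        for _ in range(200):
            groups = {i: rng.lognormal(0, 0.2, 100) for i in range(3)}
            ps.append(crt.kruskal_wallis_by_group(groups).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            crt.kruskal_wallis_by_group({0: [1.0]})
        with pytest.raises(ValueError):
            crt.kruskal_wallis_by_group({0: [1.0], 1: []})

    def test_by_finger_grouping(self, generating_model):
        session = crt.generate_cohort(crt.CohortConfig(n_participants=1, n_trials=300, epoch_boundaries=(100, 200), seed=3))[0]
        from ctree_rt.stats import response_times_by_finger

        groups = response_times_by_finger(session)
        assert sum(len(g) for g in groups.values()) == len(session)
        res = crt.kruskal_wallis_by_group(groups)
        assert 0 <= res.p_value <= 1


class TestMispredictionAnalysis:
    @pytest.fixture(scope="class")
    def cohort(self):
        return crt.generate_cohort(crt.CohortConfig(n_participants=8, n_trials=1000, seed=71))

    def test_single_context_reduction(self, cohort):
        report, means = crt.run_misprediction_analysis(cohort, [(2,)])
        assert len(report) == 1
        assert report.loc[0, "context"] == "2"
        assert set(means["context"]) == {"2"}

    def test_report_columns_and_decisions(self, cohort):
        report, _ = crt.run_misprediction_analysis(
            cohort, [(0,), (2,), (0, 1), (1, 1), (2, 1)]
        )
        assert list(report.columns) == [
            "context", "n_participants", "median_diff", "Z", "p", "bh_rejected",
        ]
        row2 = report.set_index("context").loc["2"]
        assert row2["median_diff"] > 0 and row2["bh_rejected"]

    def test_requires_two_participants(self, cohort):
        with pytest.raises(ValueError):
            crt.run_misprediction_analysis(cohort[:1], [(2,)])

    def test_insufficient_samples_excluded(self):
        cohort = crt.generate_cohort(crt.CohortConfig(n_participants=2, n_trials=60, epoch_boundaries=(20, 40), seed=72))
        report, _ = crt.run_misprediction_analysis(cohort, [(1, 1)], min_samples=50)
        assert report.loc[0, "n_participants"] == 0
        assert pd.isna(report.loc[0, "p"])
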