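"""Entropy, runs, area statistics, B/P indices, and their closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attnrl.exceptions import InvalidInputError, UndefinedIndexError
from attnrl.sequence_metrics import (
    ChoiceSequence,
    RunDistribution,
    area_significance,
    area_statistic,
    b_index,
    chi2_uniform,
    choice_entropy,
    continue_probability,
    extract_runs,
    p_index,
    sorted_reference,
    windowed_entropy,
)
from attnrl.task_library import fixture_sequences

#: printed location choice rates of the worked example subject
WORKED_RATES = (0.099, 0.266, 0.585, 0.049)


def brute_force_area(lengths1, lengths2, floor=1e-12):
    """Independent step-function trapezoid integrator over u = ln x."""
    l1, l2 = list(lengths1), list(lengths2)
    x_max = max(max(l1), max(l2))

    def ccdf(lengths, x):
        return max(sum(1 for l in lengths if l >= x) / len(lengths), floor)

    total = 0.0
    for x in range(1, x_max):
        u0, u1 = math.log(x), math.log(x + 1)
        y0 = abs(math.log(ccdf(l1, x)) - math.log(ccdf(l2, x)))
        y1 = abs(math.log(ccdf(l1, x + 1)) - math.log(ccdf(l2, x + 1)))
        total += 0.5 * (y0 + y1) * (u1 - u0)
    return total


class TestEntropy:
    def test_uniform_is_log_n(self):
        assert choice_entropy([10, 10, 10, 10]) == pytest.approx(np.log(4))

    def test_degenerate_is_zero(self):
        assert choice_entropy([0, 42, 0]) == 0.0

    def test_printed_rates_direct_summation(self):
        assert choice_entropy(WORKED_RATES) == pytest.approx(1.0426, abs=5e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            choice_entropy([0, 0, 0])


class TestBIndex:
    def test_uniform_sequence_explores(self):
        seq = ChoiceSequence(np.tile(["A", "B", "C", "D"], 100))
        assert b_index(seq, 4) == pytest.approx(0.0, abs=1e-12)

    def test_constant_sequence_exploits(self):
        assert b_index(ChoiceSequence(np.repeat("A", 50)), 4) == 1.0

    def test_printed_rates_worked_example(self):
        assert b_index(WORKED_RATES, 4) == pytest.approx(0.247, abs=0.002)

    def test_requires_two_options(self):
        with pytest.raises(InvalidInputError):
            b_index([100], 1)

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=8).filter(lambda c: sum(c) > 0))
    @settings(deadline=None, derandomize=True)
    def test_bounds_and_extremes(self, counts):
        b = b_index(counts)
        assert 0.0 <= b <= 1.0
        positive = [c for c in counts if c > 0]
        if len(set(positive)) == 1 and len(positive) == len(counts):
            assert b == pytest.approx(0.0, abs=1e-12)
        if len(positive) == 1:
            assert b == 1.0


class TestRuns:
    def test_worked_sequence_by_inspection(self):
        runs = extract_runs(ChoiceSequence.from_string("AAABABBCACD"))
        assert sorted(runs.run_lengths.tolist()) == sorted([3, 1, 1, 2, 1, 1, 1, 1])

    def test_constant_and_alternating(self):
        assert extract_runs(ChoiceSequence(np.repeat("A", 17))).run_lengths.tolist() == [17]
        alt = extract_runs(ChoiceSequence(np.tile(["A", "B"], 20)))
        assert np.all(alt.run_lengths == 1)

    def test_session_break_terminates_run(self):
        seq = ChoiceSequence(np.repeat("A", 10), session_breaks=(4,))
        assert extract_runs(seq).run_lengths.tolist() == [4, 6]

    @given(st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_lengths_partition_sequence(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 300))
        labels = rng.choice(list("ABCD"), size=n)
        breaks = tuple(sorted(set(rng.integers(1, n, size=3).tolist()))) if n > 1 else ()
        runs = extract_runs(ChoiceSequence(labels, breaks))
        assert runs.run_lengths.sum() == n

    def test_ccdf_invariants(self):
        runs = RunDistribution([1, 1, 2, 5, 5, 9])
        assert runs.ccdf_at([1])[0] == 1.0
        grid = runs.ccdf_at(np.arange(1, 12))
        assert np.all(np.diff(grid) <= 0)
        assert grid[-1] == 1e-12  # floored beyond the support


class TestSortedReference:
    def test_verbatim_example(self):
        out = sorted_reference(ChoiceSequence.from_string("AAABABBCACD"))
        assert "".join(out.labels) == "AAAAABBBCCD"

    def test_idempotent(self):
        seq = ChoiceSequence.from_string("AABBBC")
        assert "".join(sorted_reference(sorted_reference(seq)).labels) == "AABBBC"

    def test_single_label_unchanged(self):
        seq = ChoiceSequence.from_string("AAAA")
        assert "".join(sorted_reference(seq).labels) == "AAAA"


class TestAreaStatistic:
    def test_identical_distributions_zero(self):
        d = RunDistribution([1, 2, 2, 7])
        assert area_statistic(d, d) == 0.0

    def test_symmetry(self):
        d1, d2 = RunDistribution([1, 1, 2]), RunDistribution([1, 2, 2])
        assert area_statistic(d1, d2) == area_statistic(d2, d1) >= 0.0

    def test_two_point_hand_oracle(self):
        d1, d2 = RunDistribution([1, 1, 2]), RunDistribution([1, 2, 2])
        assert area_statistic(d1, d2) == pytest.approx(
            brute_force_area([1, 1, 2], [1, 2, 2]), abs=1e-10
        )

    def test_random_distributions_match_brute_force(self):
        """100 random run-distribution pairs vs the independent integrator."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            l1 = rng.integers(1, 30, size=rng.integers(1, 40)).tolist()
            l2 = rng.integers(1, 30, size=rng.integers(1, 40)).tolist()
            a = area_statistic(RunDistribution(l1), RunDistribution(l2))
            assert a == pytest.approx(brute_force_area(l1, l2), abs=1e-10)


class TestPIndex:
    def test_sorted_input_is_exactly_one(self):
        seq = fixture_sequences("sorted", 400, seed=3)
        assert p_index(seq, n_shuffles=50, seed=0).p_index == 1.0

    def test_iid_input_is_near_zero(self):
        vals = [
            p_index(fixture_sequences("iid", 1500, seed=s), n_shuffles=200, seed=s).p_index
            for s in range(20)
        ]
        assert np.mean(vals) < 0.15

    def test_sticky_markov_exceeds_iid_pairwise(self):
        for s in range(20):
            p_iid = p_index(
                fixture_sequences("iid", 1500, seed=s), n_shuffles=100, seed=s
            ).p_index
            p_markov = p_index(
                fixture_sequences("markov_stay", 1500, parameter=0.9, seed=s),
                n_shuffles=100,
                seed=s,
            ).p_index
            assert p_markov > p_iid

    def test_reproducible_and_stable_across_seeds(self):
        seq = fixture_sequences("iid", 1500, seed=0)
        a = p_index(seq, n_shuffles=1000, seed=5)
        b = p_index(seq, n_shuffles=1000, seed=5)
        assert a.p_index == b.p_index
        spread = [p_index(seq, n_shuffles=1000, seed=s).p_index for s in range(10)]
        assert np.std(spread) < 0.02

    def test_single_label_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            p_index(ChoiceSequence(np.repeat("A", 30)), n_shuffles=10, seed=0)

    def test_by_session_reports_session_means(self):
        seq = fixture_sequences("markov_stay", 600, parameter=0.8, seed=1,
                                session_length=150)
        bp = p_index(seq, n_shuffles=50, seed=0, by_session=True)
        assert bp.by_session and len(bp.session_p) == 4
        assert bp.p_index == pytest.approx(np.mean(bp.session_p))


class TestContinueProbability:
    def test_iid_uniform_is_chance_level(self):
        seq = fixture_sequences("iid", 100_000, seed=0)
        tab = continue_probability(seq, max_length=4)
        for _, row in tab.iterrows():
            se = np.sqrt(0.25 * 0.75 / max(row.n_obs, 1))
            assert row.p_continue == pytest.approx(0.25, abs=max(5 * se, 0.01))

    def test_constant_sequence_always_continues(self):
        tab = continue_probability(ChoiceSequence(np.repeat("A", 50)), max_length=5)
        assert np.all(tab.p_continue == 1.0)

    def test_markov_kernel_recovered(self):
        seq = fixture_sequences("markov_stay", 100_000, parameter=0.8, seed=2)
        tab = continue_probability(seq, max_length=4)
        for _, row in tab.iterrows():
            se = np.sqrt(0.8 * 0.2 / max(row.n_obs, 1))
            assert row.p_continue == pytest.approx(0.8, abs=max(5 * se, 0.01))

    def test_unobserved_lengths_flagged_not_imputed(self):
        tab = continue_probability(ChoiceSequence.from_string("ABAB"), max_length=5)
        assert np.isnan(tab.p_continue.iloc[-1]) and tab.n_obs.iloc[-1] == 0


class TestChi2Uniform:
    def test_worked_example_counts(self):
        stat, df, p = chi2_uniform([149, 399, 878, 74])
        assert stat == pytest.approx(1054.0, abs=1.0)
        assert df == 3 and p < 0.001

    def test_equal_counts_zero(self):
        assert chi2_uniform([25, 25, 25, 25]).statistic == 0.0

    def test_hand_arithmetic(self):
        stat, df, _ = chi2_uniform([10, 20, 30, 40])
        assert stat == pytest.approx(20.0) and df == 3

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidInputError):
            chi2_uniform([0, 0])


class TestWindowedEntropy:
    def test_constant_sequence_zero_everywhere(self):
        went = windowed_entropy(ChoiceSequence(np.repeat("A", 150)), window=50)
        assert np.all(went.entropy == 0.0) and not went.partial.any()

    def test_alternating_pair_is_ln2(self):
        went = windowed_entropy(ChoiceSequence(np.tile(["A", "B"], 100)), window=50)
        np.testing.assert_allclose(went.entropy, np.log(2), atol=1e-12)

    def test_iid_uniform_near_max_entropy(self):
        seq = fixture_sequences("iid", 1500, seed=4, session_length=150)
        went = windowed_entropy(seq, window=50)
        assert abs(went.entropy.mean() - np.log(4)) < 0.1

    def test_partial_window_flagged(self):
        went = windowed_entropy(ChoiceSequence.from_string("ABABABA"), window=4)
        assert went.partial.tolist() == [False, True]

    def test_window_too_small_rejected(self):
        with pytest.raises(InvalidInputError):
            windowed_entropy(ChoiceSequence.from_string("AB"), window=1)


class TestAreaSignificance:
    def test_identical_areas_give_zero_t(self):
        # per-session sorted sequences: empirical == sorted reference
        seq = ChoiceSequence(np.tile(np.repeat(["A", "B"], 25), 4),
                             session_breaks=(50, 100, 150))
        out = area_significance(seq, reference="sorted", n_shuffles=20, seed=0)
        assert out.t_statistic == 0.0 and out.p_value == 1.0

    def test_null_calibration_on_shuffled_sessions(self):
        hits = 0
        for rep in range(20):
            seq = fixture_sequences("iid", 600, seed=100 + rep, session_length=100)
            out = area_significance(seq, reference="shuffled", n_shuffles=60, seed=rep)
            hits += out.p_value > 0.05
        assert hits >= 18

    def test_power_on_perseverative_sessions(self):
        hits = 0
        for rep in range(20):
            seq = fixture_sequences("markov_stay", 600, parameter=0.9,
                                    seed=200 + rep, session_length=100)
            out = area_significance(seq, reference="shuffled", n_shuffles=60, seed=rep)
            hits += out.p_value < 0.05
        assert hits >= 18

    def test_overall_mode_single_unit(self):
        seq = fixture_sequences("markov_stay", 600, parameter=0.9, seed=0,
                                session_length=100)
        out = area_significance(seq, mode="overall", n_shuffles=50, seed=0)
        assert out.t_statistic is None and out.emp_areas.shape == (1,)

    def test_requires_two_sessions(self):
        with pytest.raises(InvalidInputError):
            area_significance(ChoiceSequence.from_string("ABAB"), n_shuffles=5, seed=0)
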