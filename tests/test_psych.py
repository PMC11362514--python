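import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import make_seq
from rngbench import (
    adjacency_index,
    coupon_score,
    null_score_quotient,
    phi_index,
    redundancy_index,
    repetition_gap,
    rng_index,
    runs_index,
    turning_point_index,
)
from rngbench.core import UndefinedMeasureError
from rngbench.psych import ascending_runs, pair_counts, turning_points
from rngbench.simulate import de_bruijn_sequence

seq_values = st.lists(st.integers(1, 9), min_size=5, max_size=50)


class TestRedundancyIndex:
    def test_equal_frequencies_score_zero(self):
        seq = make_seq([d for d in range(1, 10) for _ in range(20)])
        assert redundancy_index(seq) == 0.0

    def test_single_response_scores_hundred(self):
        assert redundancy_index(make_seq([7] * 50)) == 100.0

    def test_binary_three_one_split(self):
        # H(3/4, 1/4) = 0.8113 bits; R = 100*(1 - 0.8113) = 18.87
        seq = make_seq([1, 1, 1, 2], a=2)
        assert redundancy_index(seq) == pytest.approx(18.872187554086717)

    def test_unused_alphabet_symbols_count(self):
        # declared alphabet matters: 1..3 used evenly out of a=9 is redundant
        assert redundancy_index(make_seq([1, 2, 3] * 10)) > 0.0

    def test_degenerate_alphabet_rejected(self):
        with pytest.raises(ValueError):
            redundancy_index(make_seq([1, 1], a=1))


class TestRngIndex:
    def test_de_bruijn_floor(self):
        assert rng_index(de_bruijn_sequence(9, 2), lag=1) == 0.0

    def test_deterministic_transitions_ceiling(self):
        assert rng_index(make_seq([1, 2, 1, 2, 1, 2]), lag=1) == 100.0

    def test_lag2_pairs_are_interleaved(self):
        pc = pair_counts(make_seq([4, 1, 5, 6]), lag=2)
        found = {(i + 1, j + 1) for i, j in zip(*np.nonzero(pc.matrix))}
        assert found == {(4, 5), (1, 6)}

    def test_all_singleton_rows_score_zero(self):
        # every first response unique -> no pair information
        assert rng_index(make_seq([1, 2, 3, 4]), lag=1) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            rng_index(make_seq([5]), lag=1)


class TestNullScoreQuotient:
    def test_de_bruijn_floor(self):
        assert null_score_quotient(de_bruijn_sequence(9, 2)) == 0.0

    def test_three_pairs_present(self):
        assert null_score_quotient(make_seq([4, 1, 5, 6])) == pytest.approx(100 * 78 / 81)

    def test_constant_sequence(self):
        assert null_score_quotient(make_seq([1, 1, 1])) == pytest.approx(100 * 80 / 81)


class TestCouponScore:
    def test_missing_response_scores_length_plus_one(self):
        rng = np.random.default_rng(1)
        values = rng.choice([1, 2, 3, 4, 5, 6, 8, 9], size=200)  # never 7
        assert coupon_score(make_seq(values)) == 201.0

    def test_minimum_is_alphabet_size(self):
        assert coupon_score(make_seq(list(range(1, 10)))) == 9.0

    def test_hand_simulated_scan(self):
        assert coupon_score(make_seq([1, 2, 2, 3, 1, 3, 2], a=3)) == 3.5

    def test_trailing_incomplete_segment_discarded(self):
        # one full set of 3 in 4 draws, then trailing 1-1 discarded
        assert coupon_score(make_seq([1, 2, 2, 3, 1, 1], a=3)) == 4.0


class TestRepetitionGap:
    def test_single_gap(self):
        for stat in ("mean", "median", "mode"):
            assert repetition_gap(make_seq([1, 2, 1]), stat) == 2.0

    def test_pooled_gaps_and_modal_tie_break(self):
        seq = make_seq([1, 1, 2, 1])
        assert repetition_gap(seq, "mean") == 1.5
        assert repetition_gap(seq, "median") == 1.5
        assert repetition_gap(seq, "mode") == 1.0  # tie {1,2} -> smallest

    def test_no_repeats_is_undefined_not_zero(self):
        with pytest.raises(UndefinedMeasureError):
            repetition_gap(make_seq([1, 2, 3, 4]))


class TestAdjacencyIndex:
    def test_all_ascending(self):
        assert adjacency_index(make_seq([1, 2, 3]), "ascending") == 100.0
        assert adjacency_index(make_seq([1, 2, 3]), "descending") == 0.0

    def test_combined_counts_both_directions(self):
        assert adjacency_index(make_seq([7, 6, 4, 5]), "combined") == pytest.approx(200 / 3)

    def test_no_value_wrap(self):
        assert adjacency_index(make_seq([9, 1, 9]), "combined") == 0.0


class TestTurningPointIndex:
    def test_worked_example_has_two_turning_points(self):
        assert turning_points(make_seq([1, 3, 5, 4, 3, 7])) == 2

    def test_monotone_sequence_scores_zero(self):
        assert turning_point_index(make_seq([1, 2, 3, 5, 9])) == 0.0

    def test_alternating_sequence(self):
        assert turning_point_index(make_seq([1, 2, 1, 2, 1])) == 150.0

    def test_ties_are_not_turning_points(self):
        assert turning_points(make_seq([1, 2, 2, 1])) == 0


class TestRunsIndex:
    def test_worked_example_decomposition(self):
        seq = make_seq([1, 4, 7, 3, 5])
        assert ascending_runs(seq) == [3, 2]
        assert runs_index(seq) == 0.25
        assert runs_index(seq, variance="sample") == 0.5

    def test_single_run_scores_zero(self):
        assert runs_index(make_seq([1, 2, 3, 4, 5])) == 0.0

    def test_descending_gives_unit_runs(self):
        assert ascending_runs(make_seq([9, 8, 7])) == [1, 1, 1]
        assert runs_index(make_seq([9, 8, 7])) == 0.0

    def test_equal_successor_breaks_run(self):
        assert ascending_runs(make_seq([1, 2, 2, 3])) == [2, 2]


class TestPhiIndex:
    @pytest.mark.parametrize("d", [2, 3, 5, 10])
    def test_saturated_repetition_scores_zero(self, d):
        assert phi_index(make_seq([4] * 30), d) == 0.0

    def test_repetition_avoidance_is_negative(self):
        assert phi_index(make_seq([1, 2, 3] * 12), 2) < 0.0

    def test_cyclic_repeats_at_matching_span_positive(self):
        # period 3 -> every block of length 4 repeats first=last
        assert phi_index(make_seq([1, 2, 3] * 12), 4) > 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            phi_index(make_seq([1, 2, 3]), 3)

    def test_iid_null_mean_zero(self, uniform_pop):
        """Under i.i.d. uniform input the index averages 0 at every span."""
        for d in range(2, 11):
            vals = np.array([phi_index(s, d) for s in uniform_pop.sequences])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean()) < 3 * se, f"d={d}: mean {vals.mean():.3f}"


class TestOracleAgreement:
    """Every measure agrees with an independent naive reimplementation."""

    def test_all_measures_match_brute_force(self, random_short_sequences):
        for seq in random_short_sequences:
            v = seq.values.tolist()
            assert redundancy_index(seq) == pytest.approx(oracles.redundancy(v, 9))
            for lag in (1, 2):
                assert rng_index(seq, lag) == pytest.approx(oracles.rng_index(v, lag))
            assert null_score_quotient(seq) == pytest.approx(oracles.nsq(v, 9))
            assert coupon_score(seq) == pytest.approx(oracles.coupon(v, 9))
            gaps = oracles.repetition_gaps(v)
            if gaps:
                for stat in ("mean", "median", "mode"):
                    assert repetition_gap(seq, stat) == pytest.approx(
                        oracles.gap_statistic(gaps, stat)
                    )
            for mode in ("ascending", "descending", "combined"):
                assert adjacency_index(seq, mode) == pytest.approx(
                    oracles.adjacency(v, mode)
                )
            assert turning_point_index(seq) == pytest.approx(
                oracles.turning_point_index(v)
            )
            assert ascending_runs(seq) == oracles.run_lengths(v)
            assert runs_index(seq) == pytest.approx(oracles.runs_variance(v))
            for d in range(2, min(10, len(seq) - 1) + 1):
                assert phi_index(seq, d) == pytest.approx(oracles.phi(v, d, 9))


class TestProperties:
    @settings(derandomize=True, max_examples=100)
    @given(seq_values)
    def test_percentage_measures_bounded(self, values):
        seq = make_seq(values)
        for score in (
            redundancy_index(seq),
            rng_index(seq, 1),
            null_score_quotient(seq),
            adjacency_index(seq, "combined"),
        ):
            assert 0.0 <= score <= 100.0

    @settings(derandomize=True, max_examples=100)
    @given(seq_values)
    def test_coupon_and_gap_ranges(self, values):
        seq = make_seq(values)
        if set(values) == set(range(1, 10)):
            assert 9 <= coupon_score(seq) <= len(seq)
        else:  # some response never occurs -> sentinel L + 1
            assert coupon_score(seq) == len(seq) + 1
        gaps = oracles.repetition_gaps(values)
        if gaps:
            for stat in ("mean", "median", "mode"):
                assert 1 <= repetition_gap(seq, stat) <= len(seq) - 1

    @settings(derandomize=True, max_examples=100)
    @given(seq_values, st.integers(1, 2))
    def test_pair_totals_exclude_wraparound(self, values, lag):
        pc = pair_counts(make_seq(values), lag=lag)
        assert pc.total == len(values) - lag
        assert np.all(pc.matrix >= 0)

    @settings(derandomize=True, max_examples=50)
    @given(seq_values, st.randoms(use_true_random=False))
    def test_rng_index_relabeling_invariant(self, values, rnd):
        perm = list(range(1, 10))
        rnd.shuffle(perm)
        relabeled = [perm[v - 1] for v in values]
        assert rng_index(make_seq(relabeled), 1) == pytest.approx(
            rng_index(make_seq(values), 1)
        )

    def test_adjacency_not_relabeling_invariant(self):
        seq = make_seq([1, 2, 3, 4])
        relabeled = make_seq([1, 3, 5, 7])
        assert adjacency_index(seq, "combined") != adjacency_index(relabeled, "combined")

    def test_uniform_adjacency_matches_chance_rate(self, uniform_pop):
        """Combined adjacency for i.i.d. digits averages 100*16/81."""
        vals = np.array(
            [adjacency_index(s, "combined") for s in uniform_pop.sequences]
        )
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 100 * 16 / 81) < 3 * se
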