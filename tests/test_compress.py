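import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rephmm import (
    CompressionCalibration,
    ObservedSequence,
    PairRule,
    SubstitutionTable,
    calibrate,
    count_pairs,
    expand_sequence,
    expand_symbol,
    load_preprocessing,
    preprocess,
    replace_pair,
    save_preprocessing,
    select_pair,
    select_threshold,
    should_stop,
)


class TestCountPairs:
    def test_worked_example_pair_table(self, figure_sequence):
        counts = count_pairs(figure_sequence.tokens)
        assert counts[(1, 0)] == 4
        assert counts[(0, 1)] == 4
        assert counts[(0, 0)] == 3
        assert counts[(1, 1)] == 1

    @pytest.mark.parametrize("tokens", [[], [3]])
    def test_too_short_for_pairs(self, tokens):
        assert count_pairs(tokens) == {}

    def test_identical_run_counts_non_overlapping(self):
        assert count_pairs([0, 0, 0, 0]) == {(0, 0): 2}

    def test_runs_of_odd_length(self):
        # run of 5 zeros -> 2 non-overlapping (0,0) occurrences
        assert count_pairs([0] * 5) == {(0, 0): 2}


class TestSelectPair:
    def test_tie_breaks_lexicographically(self, figure_sequence):
        # (0,1) and (1,0) both occur 4 times; the smaller pair wins
        assert select_pair(count_pairs(figure_sequence.tokens)) == ((0, 1), 4)

    def test_singleton(self):
        assert select_pair({(2, 3): 5}) == ((2, 3), 5)

    def test_empty_table(self):
        assert select_pair({}) is None


class TestReplacePair:
    def test_worked_example_replacement(self, figure_sequence):
        out = replace_pair(figure_sequence.tokens, (1, 0), 2)
        np.testing.assert_array_equal(out, [2, 2, 0, 0, 2, 0, 1, 2, 0, 1])
        assert out.size == 14 - 4

    def test_absent_pair_is_identity(self):
        tokens = [0, 1, 0, 1]
        np.testing.assert_array_equal(replace_pair(tokens, (1, 1), 2), tokens)

    def test_greedy_takes_leftmost_in_run(self):
        np.testing.assert_array_equal(replace_pair([1, 1, 1], (1, 1), 2), [2, 1])

    def test_new_symbol_collision_rejected(self):
        with pytest.raises(ValueError, match="already present"):
            replace_pair([0, 1, 2], (0, 1), 2)

    def test_length_shrinks_by_count(self):
        rng = np.random.default_rng(0)
        tokens = rng.integers(0, 3, size=500)
        counts = count_pairs(tokens)
        pair, n = select_pair(counts)
        assert replace_pair(tokens, pair, 3).size == tokens.size - n


class TestStoppingCriterion:
    def test_saving_below_cost_stops(self):
        calib = CompressionCalibration(t_mv=1.0, t_mm=10.0, e=1.0)
        assert should_stop(calib, p_prev=5, pre_prev=0.0)

    def test_large_saving_continues(self):
        calib = CompressionCalibration(t_mv=1.0, t_mm=10.0, e=1.0)
        assert not should_stop(calib, p_prev=100, pre_prev=10.0)

    def test_monotone_in_pair_count(self):
        calib = CompressionCalibration(t_mv=1e-6, t_mm=1e-5, e=500.0)
        decisions = [should_stop(calib, p, 0.05) for p in range(1, 400)]
        # once the pair count is large enough to continue, larger counts continue too
        assert decisions == sorted(decisions, reverse=True)

    def test_needs_concrete_times(self):
        with pytest.raises(ValueError):
            should_stop(CompressionCalibration(), 5, 0.0)


class TestCalibrate:
    def test_matrix_matrix_dominates_matrix_vector(self):
        t_mv, t_mm = calibrate(64, repetitions=15)
        assert t_mm >= t_mv > 0

    def test_zero_repetitions_rejected(self):
        with pytest.raises(ValueError):
            calibrate(16, repetitions=0)

    def test_injected_override_is_carried(self):
        calib = CompressionCalibration(t_mv=1e-6, t_mm=1e-5)
        assert calib.t_mv == 1e-6 and calib.t_mm == 1e-5


class TestPreprocess:
    def test_all_zeros_default_stopping_trace(self):
        seq = ObservedSequence(tokens=[0] * 8, alphabet_size=1)
        stats = []
        pre = preprocess(seq, stats_out=stats)
        # suffix 0000000 -> (0,0)x3 -> 1110 -> (1,0) -> 112; then best counts repeat
        assert [s.pair_count for s in stats] == [3, 1, 1]
        entry = pre.per_threshold[0]
        np.testing.assert_array_equal(entry.tokens, [1, 1, 2])
        assert [(r.left, r.right) for r in pre.table.rules] == [(0, 0), (1, 0)]

    def test_length_two_sequence_has_single_token_remainder(self):
        seq = ObservedSequence(tokens=[1, 0], alphabet_size=2)
        pre = preprocess(seq)
        np.testing.assert_array_equal(pre.per_threshold[0].tokens, [0])
        assert pre.first_symbol == 1

    def test_equal_injected_times_stop_when_pair_count_hits_one(self):
        # with t_mv == t_mm, e = 1 and pre ~ 0, continuing requires p_prev > 1
        rng = np.random.default_rng(5)
        seq = ObservedSequence(tokens=rng.integers(0, 2, 300), alphabet_size=2)
        calib = CompressionCalibration(t_mv=1.0, t_mm=1.0, e=1.0, thresholds=(4,))
        stats = []
        pre = preprocess(seq, calib, stats_out=stats)
        replaced = len(pre.table.rules)
        # every round actually run was justified by p_prev > 1
        assert all(s.pair_count > 1 for s in stats[:replaced])

    def test_round_length_accounting(self):
        rng = np.random.default_rng(3)
        seq = ObservedSequence(tokens=rng.integers(0, 3, 2000), alphabet_size=3)
        stats = []
        pre = preprocess(seq, stats_out=stats)
        entry = pre.per_threshold[0]
        replaced = len(pre.table.rules)
        expected = seq.length - 1 - sum(s.pair_count for s in stats[:replaced])
        assert entry.tokens.size == expected

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        seq = ObservedSequence(tokens=rng.integers(0, 4, 1000), alphabet_size=4)
        a = preprocess(seq)
        b = preprocess(seq)
        np.testing.assert_array_equal(a.per_threshold[0].tokens, b.per_threshold[0].tokens)
        assert a.table == b.table

    def test_thresholds_stop_no_later_for_larger_state_counts(self):
        # measured times: t_mm grows ~N x faster than t_mv, so N_min=32 must
        # stop at least as early (fewer rules used) as N_min=2. A huge reuse
        # count makes the per-round cost term negligible, leaving the
        # t_mm/t_mv ratio in charge of the stopping point.
        rng = np.random.default_rng(9)
        seq = ObservedSequence(tokens=rng.integers(0, 2, 50_000), alphabet_size=2)
        calib = CompressionCalibration(e=1e9, thresholds=(2, 32))
        pre = preprocess(seq, calib)
        by_nmin = {e.n_min: e for e in pre.per_threshold}
        assert by_nmin[32].alphabet_size_used <= by_nmin[2].alphabet_size_used

    def test_expansion_round_trip_at_every_threshold(self):
        rng = np.random.default_rng(1)
        seq = ObservedSequence(tokens=rng.integers(0, 2, 5000), alphabet_size=2)
        calib = CompressionCalibration(t_mv=1e-6, t_mm=3e-6, e=10.0, thresholds=(2, 8))
        pre = preprocess(seq, calib)
        for entry in pre.per_threshold:
            back = expand_sequence(pre, entry.n_min)
            np.testing.assert_array_equal(back.tokens, seq.tokens)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    m=st.integers(min_value=2, max_value=6),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
    t=st.integers(min_value=1, max_value=600),
)
def test_expansion_round_trip_property(m, seed, t):
    """First symbol plus expanded remainder reproduces the input exactly."""
    rng = np.random.default_rng(seed)
    seq = ObservedSequence(tokens=rng.integers(0, m, size=t), alphabet_size=m)
    pre = preprocess(seq)
    back = expand_sequence(pre, 1)
    np.testing.assert_array_equal(back.tokens, seq.tokens)
    entry = pre.per_threshold[0]
    assert entry.alphabet_size_used <= m + len(pre.table.rules)
    if entry.tokens.size:
        assert entry.tokens.max() < entry.alphabet_size_used


class TestExpandSymbol:
    def test_original_symbol_is_base_case(self):
        table = SubstitutionTable(original_alphabet_size=2)
        np.testing.assert_array_equal(expand_symbol(0, table), [0])

    def test_one_level(self):
        table = SubstitutionTable(2, (PairRule(2, 1, 0),))
        np.testing.assert_array_equal(expand_symbol(2, table), [1, 0])

    def test_two_levels(self):
        table = SubstitutionTable(2, (PairRule(2, 0, 0), PairRule(3, 2, 2)))
        np.testing.assert_array_equal(expand_symbol(3, table), [0, 0, 0, 0])

    def test_unknown_symbol_rejected(self):
        table = SubstitutionTable(original_alphabet_size=2)
        with pytest.raises(ValueError):
            expand_symbol(5, table)

    def test_rule_ordering_enforced(self):
        with pytest.raises(ValueError):
            SubstitutionTable(2, (PairRule(3, 0, 1),))


class TestPersistence:
    @pytest.fixture
    def saved(self, tmp_path):
        rng = np.random.default_rng(2)
        seq = ObservedSequence(tokens=rng.integers(0, 3, 800), alphabet_size=3)
        calib = CompressionCalibration(t_mv=1e-6, t_mm=2e-6, e=100.0, thresholds=(4, 16))
        pre = preprocess(seq, calib)
        save_preprocessing(pre, tmp_path / "pp")
        return pre, tmp_path / "pp"

    def test_round_trip_exact(self, saved):
        pre, directory = saved
        loaded = load_preprocessing(directory, 4)
        orig = select_threshold(pre, 4)
        np.testing.assert_array_equal(loaded.per_threshold[0].tokens, orig.tokens)
        assert loaded.table == pre.table
        assert loaded.first_symbol == pre.first_symbol

    def test_selects_largest_threshold_not_exceeding(self, saved):
        _, directory = saved
        loaded = load_preprocessing(directory, 8)
        assert loaded.per_threshold[0].n_min == 4

    def test_fallback_to_smallest_with_warning(self, saved):
        _, directory = saved
        with pytest.warns(UserWarning, match="falling back"):
            loaded = load_preprocessing(directory, 2)
        assert loaded.per_threshold[0].n_min == 4

    def test_missing_files_named(self, saved, tmp_path):
        _, directory = saved
        (directory / "rules.txt").unlink()
        with pytest.raises(FileNotFoundError, match="rules.txt"):
            load_preprocessing(directory, 4)

    def test_no_thresholds_is_a_format_error(self, tmp_path):
        d = tmp_path / "empty"
        d.mkdir()
        (d / "meta.json").write_text(
            '{"format_version": 1, "original_length": 5, "original_alphabet_size": 2,'
            ' "first_symbol": 0, "e_used": 1.0, "thresholds": []}'
        )
        with pytest.raises(ValueError, match="no stored thresholds"):
            load_preprocessing(d, 4)
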