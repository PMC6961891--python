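"""Break-point engine: enumeration, scoring, ranking, weighting."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import shiftdetect as sd
from shiftdetect.engine import BreakCombination, break_weights
from shiftdetect.ricker import deterministic_trajectory


def brute_force_break_sets(n_points: int, min_segment: int) -> set:
    """Oracle: filter all subsets of candidate cut positions directly."""
    admissible = set()
    positions = range(1, n_points)
    for size in range(0, n_points // min_segment):
        for combo in itertools.combinations(positions, size):
            bounds = (0, *combo, n_points)
            if all(
                bounds[i + 1] - bounds[i] >= min_segment
                for i in range(len(bounds) - 1)
            ):
                admissible.add(combo)
    return admissible


class TestEnumeration:
    def test_seven_points_only_empty(self):
        assert sd.enumerate_combinations(7, 4) == [()]

    def test_eight_points_single_midpoint_cut(self):
        assert sd.enumerate_combinations(8, 4) == [(), (4,)]

    def test_twelve_points_seven_combinations(self):
        combos = sd.enumerate_combinations(12, 4)
        assert len(combos) == 7
        by_size = {k: len(list(g)) for k, g in itertools.groupby(combos, len)}
        assert by_size == {0: 1, 1: 5, 2: 1}

    @pytest.mark.parametrize("min_segment", [4, 5, 6])
    @pytest.mark.parametrize("n_points", [8, 11, 14, 16])
    def test_matches_brute_force(self, n_points, min_segment):
        got = set(sd.enumerate_combinations(n_points, min_segment))
        assert got == brute_force_break_sets(n_points, min_segment)

    @given(n_points=st.integers(6, 14), min_segment=st.integers(4, 6))
    def test_matches_brute_force_property(self, n_points, min_segment):
        got = set(sd.enumerate_combinations(n_points, min_segment))
        assert got == brute_force_break_sets(n_points, min_segment)

    def test_canonical_order(self):
        combos = sd.enumerate_combinations(20, 4)
        key = [(len(c), c) for c in combos]
        assert key == sorted(key)

    def test_max_breaks_cap(self):
        assert all(len(c) <= 1 for c in sd.enumerate_combinations(20, 4, 1))

    def test_too_short_series_raises(self):
        with pytest.raises(sd.SeriesError):
            sd.enumerate_combinations(3, 4)


class TestAkaikeWeights:
    def test_two_unit_gap(self):
        w = sd.akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_ties_split_evenly(self):
        assert sd.akaike_weights([5.5, 5.5]) == pytest.approx([0.5, 0.5])

    def test_single_score(self):
        assert sd.akaike_weights([42.0]) == pytest.approx([1.0])

    def test_nonfinite_scores_excluded(self):
        w = sd.akaike_weights([1.0, math.inf, 3.0])
        assert w[1] == 0.0
        assert w.sum() == pytest.approx(1.0)

    def test_all_nonfinite_raises(self):
        with pytest.raises(ValueError):
            sd.akaike_weights([math.inf, math.nan])

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=12),
        st.floats(-50, 50),
    )
    def test_sum_to_one_and_shift_invariant(self, scores, shift):
        w = sd.akaike_weights(scores)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        w2 = sd.akaike_weights([s + shift for s in scores])
        assert w2 == pytest.approx(w, abs=1e-9)


def _combo(breaks):
    return BreakCombination(breaks=tuple(breaks), segment_fits=(), total_ic=0.0)


class TestBreakWeights:
    def test_single_containing_combination(self):
        bw = break_weights([_combo(()), _combo((7,))], [0.4, 0.6])
        assert bw == {7: pytest.approx(0.6)}

    def test_hand_summation(self):
        combos = [_combo((3,)), _combo((3, 9)), _combo(())]
        bw = break_weights(combos, [0.3, 0.5, 0.2])
        assert bw[3] == pytest.approx(0.8)
        assert bw[9] == pytest.approx(0.5)

    def test_weight_one_requires_membership_everywhere(self):
        combos = [_combo((5,)), _combo((5, 11))]
        bw = break_weights(combos, [0.7, 0.3])
        assert bw[5] == pytest.approx(1.0)
        assert bw[11] < 1.0


class TestClassifyBreak:
    @pytest.mark.parametrize(
        "weight,label",
        [(0.85, "supported"), (0.1, "erroneous"), (0.56, "ambiguous"),
         (0.8, "ambiguous"), (0.2, "ambiguous")],
    )
    def test_decision_rules(self, weight, label):
        assert sd.classify_break(weight) == label

    def test_domain_error(self):
        with pytest.raises(ValueError):
            sd.classify_break(1.2)
        with pytest.raises(ValueError):
            sd.classify_break(-0.1)


class TestScoreCombination:
    def test_empty_break_set_equals_whole_series_ic(self, one_break_series):
        series = one_break_series.series
        combo = sd.score_combination(series, ())
        fit = sd.fit_ricker(series, series.first_year, series.last_year)
        assert combo.total_ic == pytest.approx(sd.segment_ic(fit, "AICc"))

    def test_total_is_sum_of_segment_scores(self, one_break_series):
        series = one_break_series.series
        combo = sd.score_combination(series, (10,))
        assert combo.total_ic == pytest.approx(
            sum(f.ic for f in combo.segment_fits), rel=1e-15
        )

    def test_segments_partition_transitions(self, one_break_series):
        series = one_break_series.series
        combo = sd.score_combination(series, (6, 12))
        assert sum(f.n_obs for f in combo.segment_fits) == len(series) - 1
        # consecutive segments share their boundary year
        for a, b in zip(combo.segment_fits, combo.segment_fits[1:]):
            assert a.end_year == b.start_year

    def test_true_split_beats_no_break_on_shifted_series(self):
        # two noiseless regimes with a large K shift
        p1 = sd.RickerParams(1.5, 1000.0)
        p2 = sd.RickerParams(1.5, 3000.0)
        first = deterministic_trajectory(1500.0, p1, 10)
        second = deterministic_trajectory(
            sd.predict_next(first[-1], p2), p2, 10
        )
        series = sd.PopulationTimeSeries(
            years=np.arange(1, 21), abundances=np.concatenate([first, second])
        )
        split = sd.score_combination(series, (10,))
        whole = sd.score_combination(series, ())
        assert split.total_ic < whole.total_ic


class TestRankCombinations:
    def test_no_shift_series_ranks_empty_set_first(self, noiseless_series):
        series, _ = noiseless_series(r=1.5, k=2000.0, n1=3000.0, length=20)
        ranking = sd.rank_combinations(series)
        assert ranking.best.breaks == ()

    def test_delta_of_top_is_zero_and_sorted(self, one_break_series):
        ranking = sd.rank_combinations(one_break_series.series)
        assert ranking.delta_ic[0] == 0.0
        assert list(ranking.delta_ic) == sorted(ranking.delta_ic)

    def test_weights_sum_to_one_after_renormalization(self, one_break_series):
        ranking = sd.rank_combinations(one_break_series.series)
        assert sum(ranking.akaike_weight) == pytest.approx(1.0, abs=1e-9)

    def test_break_weights_in_unit_interval(self, one_break_series):
        ranking = sd.rank_combinations(one_break_series.series)
        assert all(0.0 <= w <= 1.0 + 1e-9 for w in ranking.break_weights.values())

    def test_detects_planted_break(self, one_break_series):
        ranking = sd.rank_combinations(one_break_series.series)
        assert 10 in ranking.best.breaks
        assert ranking.break_weights[10] > 0.8

    def test_deterministic_output(self, one_break_series):
        r1 = sd.rank_combinations(one_break_series.series)
        r2 = sd.rank_combinations(one_break_series.series)
        assert [c.breaks for c in r1.combinations] == [
            c.breaks for c in r2.combinations
        ]
        assert r1.akaike_weight == r2.akaike_weight
        assert r1.break_weights == r2.break_weights

    def test_no_break_rss_bounds_best_split_rss(self, one_break_series):
        series = one_break_series.series
        whole = sd.fit_ricker(series, series.first_year, series.last_year)
        splits = [
            sd.score_combination(series, (y,))
            for y in range(series.first_year + 4, series.last_year - 3)
        ]
        best_split_rss = min(
            sum(f.rss for f in c.segment_fits) for c in splits if c.scorable
        )
        assert whole.rss >= best_split_rss - 1e-9

    def test_aicc_excludes_leading_four_point_block(self, noiseless_series):
        series, _ = noiseless_series(length=8, n1=3000.0, k=2000.0, r=1.0)
        aicc = sd.rank_combinations(series, sd.DsdConfig(criterion="AICc"))
        assert [c.breaks for c in aicc.combinations] == [()]
        assert aicc.n_unscorable == 1
        aic = sd.rank_combinations(series, sd.DsdConfig(criterion="AIC"))
        assert aic.n_enumerated == 2
        assert aic.n_unscorable == 0

    def test_equivalence_set_within_delta(self, one_break_series):
        ranking = sd.rank_combinations(one_break_series.series)
        deltas = dict(
            zip((c.breaks for c in ranking.combinations), ranking.delta_ic)
        )
        for combo in ranking.equivalence_set:
            assert deltas[combo.breaks] < 2.0


class TestConfigValidation:
    def test_aicc_with_tiny_min_segment_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.DsdConfig(criterion="AICc", min_segment=3)

    def test_unknown_criterion_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.DsdConfig(criterion="BIC")

    def test_defaults_match_reference_settings(self):
        cfg = sd.DsdConfig()
        assert (
            cfg.criterion,
            cfg.min_segment,
            cfg.equivalence_delta,
            cfg.prune_threshold,
            cfg.supported_threshold,
            cfg.erroneous_threshold,
        ) == ("AICc", 4, 2.0, 0.001, 0.8, 0.2)
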