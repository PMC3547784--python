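"""Calibration, over/underconfidence, resolution and their invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from confcal import (
    DEFAULT_EDGES,
    bin_confidence,
    calibration_score,
    normalised_resolution,
    over_underconfidence,
    resolution,
    summarise,
)
from helpers import adversarial_records, brute_force_stats, make_records, random_record_table


class TestBinning:
    def test_single_top_record(self):
        bins = bin_confidence(make_records([100], [True]))
        top = bins[-1]
        assert (top.n, top.p_bar, top.e_bar) == (1, 1.0, 1.0)
        assert sum(b.n for b in bins) == 1

    def test_two_records_same_bin(self):
        bins = bin_confidence(make_records([55, 55], [True, False]))
        b = next(b for b in bins if b.lower == 0.5)
        assert (b.n, b.p_bar, b.e_bar) == (2, 0.55, 0.5)

    def test_empty_bins_retained_and_counts_match_linear_scan(self):
        rng = np.random.default_rng(3)
        records = make_records(
            rng.integers(0, 101, 50).tolist(), (rng.random(50) < 0.7).tolist()
        )
        bins = bin_confidence(records)
        assert len(bins) == len(DEFAULT_EDGES) - 1
        assert sum(b.n for b in bins) == 50
        # brute-force count per bin
        probs = records["confidence"].to_numpy() / 100.0
        for b in bins:
            expected = sum(
                1
                for p in probs
                if b.lower <= p < b.upper or (b.upper == 1.0 and p == 1.0)
            )
            assert b.n == expected

    def test_rating_59_falls_in_the_50s_decile(self):
        bins = bin_confidence(make_records([59], [True]))
        b = next(b for b in bins if b.n)
        assert (b.lower, b.upper) == (0.5, 0.6)

    def test_errors(self):
        with pytest.raises(ValueError):
            bin_confidence(make_records([], []))
        with pytest.raises(ValueError):
            bin_confidence(make_records([50], [True]), edges=[0.1, 0.5, 1.0])
        with pytest.raises(ValueError):
            bin_confidence(make_records([50], [True]), edges=[0.0, 0.5, 0.5, 1.0])


class TestAnalyticCases:
    def test_adversarial_responder_has_worst_calibration(self):
        s = summarise(adversarial_records(5, 5))
        assert s.calibration == 1.0

    def test_perfectly_calibrated_responder_scores_zero(self):
        records = make_records(
            [80] * 10 + [60] * 10,
            [True] * 8 + [False] * 2 + [True] * 6 + [False] * 4,
        )
        s = summarise(records)
        assert s.calibration == 0.0
        assert s.over_under == pytest.approx(0.0, abs=1e-15)

    def test_adversarial_responder_has_perfect_resolution(self):
        s = summarise(adversarial_records(5, 5))
        assert s.resolution == pytest.approx(0.25)
        assert s.normalised_resolution == 1.0
        assert s.over_under == pytest.approx(0.0, abs=1e-15)

    def test_three_bin_direct_formula_example(self):
        # bins: [0.5,0.6) n=2 pbar=.55 ebar=.5; [0.7,0.8) n=1 pbar=.75 ebar=1;
        # [0.9,1] n=1 pbar=.95 ebar=1 -> (2*.0025 + .0625 + .0025)/4 = 0.0175
        records = make_records([55, 55, 75, 95], [True, False, True, True])
        assert summarise(records).calibration == pytest.approx(0.0175, abs=1e-15)

    def test_single_bin_has_zero_resolution(self):
        s = summarise(make_records([72, 75, 78], [True, False, True]))
        assert s.resolution == 0.0
        assert s.normalised_resolution == 0.0

    def test_over_underconfidence_arithmetic(self):
        records = make_records([70] * 10, [True] * 8 + [False] * 2)
        assert over_underconfidence(records) == pytest.approx(-0.10)
        assert over_underconfidence(make_records([100] * 4, [True] * 4)) == 0.0

    def test_degenerate_knowledge_index_flagged(self):
        s = summarise(make_records([60, 90], [True, True]))
        assert s.e_bar == 1.0
        assert s.normalised_resolution == 0.0
        assert s.degenerate

    def test_resolution_exceeding_knowledge_index_rejected(self):
        bins = bin_confidence(make_records([55, 95], [True, False]))
        with pytest.raises(ValueError):
            normalised_resolution(0.5, 0.9)
        # consistent inputs pass
        assert resolution(bins, 0.5, 2) <= 0.25 + 1e-12


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_binned_statistics_match_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        records = random_record_table(rng)
        s = summarise(records)
        cal, res, nrs, degenerate = brute_force_stats(
            records["confidence"].tolist(), records["correct"].tolist(), DEFAULT_EDGES
        )
        assert s.calibration == pytest.approx(cal, abs=1e-12)
        assert s.resolution == pytest.approx(res, abs=1e-12)
        assert s.normalised_resolution == pytest.approx(nrs, abs=1e-12)
        assert s.degenerate == degenerate


class TestInvariants:
    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 100), st.booleans()), min_size=1, max_size=120
        )
    )
    def test_bounds_on_random_inputs(self, pairs):
        records = make_records([c for c, _ in pairs], [k for _, k in pairs])
        s = summarise(records)
        assert 0.0 <= s.calibration <= 1.0
        assert -1.0 <= s.over_under <= 1.0
        assert 0.0 <= s.resolution <= s.e_bar * (1 - s.e_bar) + 1e-12
        assert 0.0 <= s.normalised_resolution <= 1.0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 100), st.booleans()), min_size=2, max_size=60
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, pairs, rnd):
        shuffled = list(pairs)
        rnd.shuffle(shuffled)
        s1 = summarise(make_records([c for c, _ in pairs], [k for _, k in pairs]))
        s2 = summarise(make_records([c for c, _ in shuffled], [k for _, k in shuffled]))
        assert s1.calibration == pytest.approx(s2.calibration, abs=1e-12)
        assert s1.resolution == pytest.approx(s2.resolution, abs=1e-12)
        assert s1.over_under == pytest.approx(s2.over_under, abs=1e-12)

    def test_scale_invariance_0_100_vs_probability(self):
        rng = np.random.default_rng(5)
        conf = rng.integers(0, 101, 40)
        corr = (rng.random(40) < 0.6).tolist()
        s100 = summarise(make_records(conf.tolist(), corr))
        s01 = summarise(make_records((conf / 100.0).tolist(), corr))
        assert s100.calibration == pytest.approx(s01.calibration, abs=1e-15)
        assert s100.p_bar == pytest.approx(s01.p_bar, abs=1e-15)
        assert s100.resolution == pytest.approx(s01.resolution, abs=1e-15)

    def test_summary_internal_consistency(self, study_records):
        s = summarise(study_records)
        assert s.over_under == pytest.approx(s.p_bar - s.e_bar, abs=1e-15)
        assert sum(b.n for b in s.bins) == s.n == len(study_records)
        occupied = [b for b in s.bins if b.n]
        for b in occupied:
            assert b.lower <= b.p_bar <= b.upper
            assert 0.0 <= b.e_bar <= 1.0
        assert calibration_score(s.bins, s.n) == s.calibration
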