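import numpy as np
import pytest
from hypothesis import given, strategies as st

from consenconv import (
    CorrectionMode,
    ScanConfig,
    TripletProfile,
    apply_bonferroni,
    background_p,
    binomial_tail,
    bonferroni_threshold,
    count_comparisons,
    scan_profile,
    window_pvalue,
)
from oracles import binom_tail_oracle, scan_oracle


def make_profile(flags, columns=None):
    flags = np.asarray(flags, dtype=bool)
    if columns is None:
        columns = np.arange(flags.size)
    return TripletProfile(
        target_id="t",
        parent_a_id="a",
        parent_b_id="b",
        columns=np.asarray(columns),
        matches_b=flags,
    )


class TestBinomialTail:
    def test_zero_matches_has_full_mass(self):
        assert binomial_tail(17, 0, 0.3) == 1.0

    def test_all_matches_is_p_to_the_n(self):
        assert binomial_tail(5, 5, 0.5) == pytest.approx(0.03125, abs=0)

    def test_three_term_summation_example(self):
        # direct summation over m = 8, 9, 10 at p = 0.3
        expected = binom_tail_oracle(10, 8, 0.3)
        assert expected == pytest.approx(1.5904e-3, rel=1e-4)
        assert binomial_tail(10, 8, 0.3) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [(5, 6, 0.5), (5, -1, 0.5), (5, 2, 0.0), (5, 2, 1.0)])
    def test_domain_violations(self, bad):
        with pytest.raises(ValueError):
            binomial_tail(*bad)

    def test_monotone_in_matches_and_background(self):
        tails = [binomial_tail(20, m, 0.3) for m in range(21)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        by_p = [binomial_tail(20, 9, p) for p in np.linspace(0.05, 0.95, 19)]
        assert all(a <= b for a, b in zip(by_p, by_p[1:]))


class TestBackgroundP:
    def test_direct_ratio(self):
        flags = [True] + [False] * 19
        # window [5, 10): the single match lies outside -> 1/15
        assert background_p(make_profile(flags), 5, 10) == pytest.approx(1 / 15)

    def test_zero_match_clamp(self):
        flags = [False] * 20
        assert background_p(make_profile(flags), 5, 10) == pytest.approx(1 / 30)

    def test_all_match_clamp_single_outside_site(self):
        flags = [True] * 10
        assert background_p(make_profile(flags), 0, 9) == pytest.approx(0.5)

    def test_window_covering_everything_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            background_p(make_profile([True] * 10), 0, 10)


class TestWindowPvalue:
    def test_hand_computed_window(self):
        # L=20, window of 5 all-matches, 1 of the 15 outside sites matches
        flags = [False] * 5 + [True] * 5 + [False] * 9 + [True]
        stat = window_pvalue(make_profile(flags), 5, 10)
        assert stat.N == 5 and stat.M == 5
        assert stat.p == pytest.approx(1 / 15)
        assert stat.binom_tail == pytest.approx((1 / 15) ** 5, rel=1e-9)
        assert stat.P_LoverN == pytest.approx(4 * (1 / 15) ** 5, rel=1e-9)
        assert stat.P_LminusN == pytest.approx(15 * (1 / 15) ** 5, rel=1e-9)

    def test_empty_window_caps_both_corrections_at_one(self):
        stat = window_pvalue(make_profile([False] * 6 + [True]), 0, 3)
        assert stat.binom_tail == 1.0
        assert stat.P_LoverN == 1.0 and stat.P_LminusN == 1.0

    def test_upper_bound_when_sliding_windows_outnumber_blocks(self):
        # whenever N(L-N) >= L the L-N factor dominates L/N
        rng = np.random.default_rng(5)
        for _ in range(200):
            L = int(rng.integers(5, 40))
            flags = rng.random(L) < rng.uniform(0.05, 0.9)
            s = int(rng.integers(0, L - 3))
            e = int(rng.integers(s + 3, min(L, s + 3 + 15) + 1))
            if e - s >= L:
                continue
            stat = window_pvalue(make_profile(flags), s, e)
            if stat.N * (L - stat.N) >= L:
                assert stat.P_LminusN >= stat.P_LoverN


class TestScan:
    def test_no_matches_reports_nothing(self):
        assert scan_profile(make_profile([False] * 30)) == []

    def test_short_profile_reports_nothing(self):
        assert scan_profile(make_profile([True] * 3), ScanConfig(min_window=3)) == []

    def test_single_planted_run_recovered(self):
        flags = [False] * 8 + [True] * 5 + [False] * 7
        columns = np.arange(100, 120)
        segs = scan_profile(make_profile(flags, columns))
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.stat.start_idx, seg.stat.end_idx) == (8, 13)
        # 1-based inclusive alignment coordinates of the run
        assert (seg.aln_start, seg.aln_end) == (109, 113)
        expected = scan_oracle(flags)
        assert [(s.stat.start_idx, s.stat.end_idx) for s in segs] == expected

    def test_out_of_window_background_sharpens_planted_signal(self):
        # with every match inside the window, excluding it lowers p and
        # hence the tail relative to the whole-profile background
        flags = [False] * 10 + [True] * 6 + [False] * 10
        prof = make_profile(flags)
        improved = window_pvalue(prof, 10, 16, whole_profile_p=False)
        original = window_pvalue(prof, 10, 16, whole_profile_p=True)
        assert improved.p < original.p
        assert improved.binom_tail <= original.binom_tail

    @given(data=st.data())
    def test_equals_exhaustive_enumeration(self, data):
        L = data.draw(st.integers(min_value=4, max_value=30))
        flags = data.draw(
            st.lists(st.booleans(), min_size=L, max_size=L)
        )
        mode = data.draw(st.sampled_from(list(CorrectionMode)))
        config = ScanConfig(correction_mode=mode, require_both=True)
        got = [
            (s.stat.start_idx, s.stat.end_idx)
            for s in scan_profile(make_profile(flags), config)
        ]
        assert got == scan_oracle(flags, correction=mode.value)

    def test_reported_segments_never_overlap(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            flags = rng.random(40) < 0.4
            segs = scan_profile(make_profile(flags))
            spans = [(s.stat.start_idx, s.stat.end_idx) for s in segs]
            for i, (s1, e1) in enumerate(spans):
                for s2, e2 in spans[i + 1 :]:
                    assert e1 <= s2 or e2 <= s1


class TestCorrections:
    def test_bonferroni_threshold_identity_and_errors(self):
        assert bonferroni_threshold(1, 0.05) == 0.05
        assert bonferroni_threshold(4950, 0.05) == pytest.approx(1.0101e-5, rel=1e-4)
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)

    def test_comparison_counts(self):
        assert count_comparisons(60, 40, "consensus") == 100
        assert count_comparisons(100, 0, "pairs") == 4950
        assert count_comparisons(3, 0, "triplets_onepop") == 1
        assert count_comparisons(2, 2, "triplets_twopop") == 8
        with pytest.raises(ValueError):
            count_comparisons(2, 2, "nope")

    def test_growth_orders(self):
        # consensus linear, twopop and onepop cubic in sequence counts
        assert count_comparisons(200, 200, "consensus") == 2 * count_comparisons(100, 100, "consensus")
        assert count_comparisons(20, 20, "triplets_twopop") == 2 * 20 * 19 * 20
        assert count_comparisons(1000, 0, "triplets_onepop") == 166_167_000

    def test_corrected_p_never_below_uncorrected(self):
        flags = [False] * 8 + [True] * 5 + [False] * 7
        config = ScanConfig()
        (seg,) = scan_profile(make_profile(flags), config)
        boosted = apply_bonferroni(seg, 50, config)
        assert boosted.P_LoverN_corrected >= seg.stat.P_LoverN
        assert boosted.P_LminusN_corrected >= seg.stat.P_LminusN
        assert boosted.k == 50
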