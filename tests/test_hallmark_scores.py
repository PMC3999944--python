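"""Unit and property tests for the seven hallmark sub-scores."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from shatterscan import (
    CNVCall,
    GenomeModel,
    InsertionCall,
    LOHCall,
    MutatedRegion,
    ScanConfig,
    TranslocationCall,
    chromosome_localization_score,
    cn_oscillations,
    cnv_score,
    count_significant,
    genome_localization_score,
    heterozygosity_score,
    insertion_score,
    tp53_scan,
    tp53_score,
    translocation_score,
    translocation_spread,
)
from shatterscan.hallmark_scores import CNStateTally


class TestGenomeLocalization:
    def test_density_at_or_below_mean_scores_zero(self):
        assert genome_localization_score(0.5, 1.0, 0.2) == 0.0
        assert genome_localization_score(1.0, 1.0, 0.2) == 0.0

    def test_zero_sd_scores_zero(self):
        assert genome_localization_score(2.0, 1.0, 0.0) == 0.0

    def test_z_196_scores_095(self):
        # z = 1.96 -> right tail p ~ 0.025 -> (0.5 - p)/0.5 ~ 0.950
        assert genome_localization_score(1.96, 0.0, 1.0) == pytest.approx(0.950, abs=5e-4)

    def test_matches_normal_cdf_oracle_and_is_monotone(self):
        zs = np.linspace(0.01, 6.0, 80)
        scores = [genome_localization_score(z, 0.0, 1.0) for z in zs]
        for z, s in zip(zs, scores):
            assert s == pytest.approx(2 * sps.norm.cdf(z) - 1, abs=1e-12)
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestChromosomeLocalization:
    def test_observed_equal_expected_scores_zero(self):
        assert chromosome_localization_score(4, 100, 0.04) == 0.0

    def test_observed_below_expected_scores_zero(self):
        assert chromosome_localization_score(2, 100, 0.04) == 0.0

    def test_twofold_enrichment_matches_chi2_oracle(self):
        # O=8, E=4: chi2 = 4 -> lower tail of chi2(1) ~ 0.9545
        assert chromosome_localization_score(8, 100, 0.04) == pytest.approx(0.9545, abs=1e-4)

    def test_zero_expectation(self):
        assert chromosome_localization_score(3, 100, 0.0) == 1.0
        assert chromosome_localization_score(0, 100, 0.0) == 0.0


class TestCountSignificant:
    def test_identical_values_are_all_significant(self):
        assert count_significant([5, 5, 5]) == 3

    def test_mild_low_value_is_retained(self):
        # z of 1 in {10, 10, 1} is about -1.41 > -2
        assert count_significant([10, 10, 1]) == 3

    def test_strong_low_outlier_is_excluded(self):
        # nine 5s and a 0: z of 0 is exactly -3
        assert count_significant([5] * 9 + [0]) == 9

    def test_empty_input(self):
        assert count_significant([]) == 0


class TestCNOscillations:
    def test_single_deletion_oscillates_twice(self):
        tally = cn_oscillations([CNVCall("1", 100, 200, 1, 1.0)])
        assert tally.oscillations == {1: 2}
        assert tally.total_oscillations == 2

    def test_eight_disjoint_deletions_give_sixteen(self):
        cnvs = [CNVCall("1", 1000 * i, 1000 * i + 400, 1, 1.0) for i in range(1, 9)]
        tally = cn_oscillations(cnvs)
        assert tally.oscillations == {1: 16}
        assert tally.total_oscillations == 16

    def test_no_cnvs_no_oscillations(self):
        tally = cn_oscillations([])
        assert tally.oscillations == {} and tally.total_oscillations == 0

    def test_normal_copy_segments_are_ignored(self):
        tally = cn_oscillations([CNVCall("1", 100, 200, 2, 1.0)])
        assert tally.total_oscillations == 0

    def test_abutting_different_states_share_one_transition(self):
        cnvs = [CNVCall("1", 100, 200, 1, 1.0), CNVCall("1", 201, 300, 3, 1.0)]
        tally = cn_oscillations(cnvs)
        # normal->1, 1->3, 3->normal: three events, the middle credited twice
        assert tally.total_oscillations == 3
        assert tally.oscillations == {1: 2, 3: 2}

    def test_same_state_overlaps_merge(self):
        cnvs = [CNVCall("1", 100, 250, 1, 1.0), CNVCall("1", 200, 300, 1, 1.0)]
        tally = cn_oscillations(cnvs)
        assert tally.segment_counts == {1: 1}
        assert tally.total_oscillations == 2

    def test_cross_state_overlap_resolved_by_amplitude(self):
        cnvs = [CNVCall("1", 100, 300, 1, 1.0), CNVCall("1", 200, 250, 0, 1.0)]
        tally = cn_oscillations(cnvs)
        # homozygous deletion wins the overlap, splitting the hemizygous one
        assert tally.segment_counts == {1: 2, 0: 1}


class TestCNVScore:
    def test_no_aberrant_segments(self):
        assert cnv_score(cn_oscillations([])) == 0.0

    def test_single_state_sixteen_oscillations(self):
        # x = 16/2 = 8 -> (1/1)(1 - 1/(1 + 3)) = 0.75
        tally = CNStateTally({1: 16}, {1: 8}, 16)
        assert cnv_score(tally) == pytest.approx(0.75)

    def test_one_busy_state_beats_three_quiet_states(self):
        one = CNStateTally({1: 15}, {1: 7}, 15)
        three = CNStateTally({0: 5, 1: 5, 3: 5}, {0: 2, 1: 2, 3: 2}, 15)
        assert cnv_score(one) > cnv_score(three)

    def test_single_isolated_segment_scores_zero(self):
        # x = 2/2 = 1 -> second factor 0
        assert cnv_score(cn_oscillations([CNVCall("1", 100, 200, 1, 1.0)])) == 0.0

    def test_non_increasing_in_state_count_at_fixed_total(self):
        scores = []
        for n_states in (1, 2, 3, 5):
            osc = {s: 30 // n_states for s in range(n_states)}
            scores.append(cnv_score(CNStateTally(osc, dict(osc), 30)))
        assert all(b <= a for a, b in zip(scores, scores[1:]))


class TestTranslocationSpread:
    def test_regular_breakpoints(self):
        assert translocation_spread([100, 200, 300, 400], expected_spread=1e6) == 100.0

    def test_high_outlier_separation_is_dropped(self):
        # nine separations of 10, one of 999910 (z = 3 > 2)
        bps = [10 * i for i in range(10)] + [1_000_000]
        assert translocation_spread(bps, expected_spread=1e6) == pytest.approx(10.0)

    def test_single_breakpoint_is_neutral(self):
        assert translocation_spread([42], expected_spread=777.0) == 777.0


def _region(chrom: str, translocations, start=1, end=1_000_000) -> MutatedRegion:
    return MutatedRegion(chrom=chrom, start=start, end=end, breakpoint_count=1,
                         region_density=1e-6, translocations=tuple(translocations))


def _to_partner(partner: str, positions, src=(1000, 2000)) -> TranslocationCall:
    return TranslocationCall("1", src[0], src[1], partner, positions[0], positions[1], 1.0)


class TestTranslocationScore:
    def test_nine_significant_partners_zero_the_score(self, toy_genome):
        calls = [
            _to_partner(str(p), (100_000 * p, 100_000 * p + 500))
            for p in range(2, 11)  # nine partners, equal counts
        ]
        res = translocation_score(_region("1", calls), toy_genome)
        assert res.n_significant == 9
        assert res.first_term == 0.0
        assert res.score == 0.0

    def test_single_partner_first_term_is_one(self, toy_genome):
        calls = [_to_partner("2", (500_000 + 2000 * i, 501_000 + 2000 * i)) for i in range(4)]
        res = translocation_score(_region("1", calls), toy_genome)
        assert res.n_significant == 1
        assert res.first_term == 1.0
        assert res.score > 0.0

    def test_weighted_sum_of_one_zeroes_second_term(self, toy_genome):
        # a single translocation whose partner breakpoints sit exactly at the
        # uniform expectation gives weighted_sum ~ 1 -> log2(2) = 1 -> 0
        region = _region("1", [_to_partner("2", (3_333_333, 6_666_667))])
        res = translocation_score(region, toy_genome)
        assert res.weighted_sum == pytest.approx(1.0, rel=1e-3)
        assert res.second_term == pytest.approx(0.0, abs=1e-3)

    def test_no_translocations_scores_zero(self, toy_genome):
        assert translocation_score(_region("1", []), toy_genome).score == 0.0

    def test_clustered_beats_dispersed(self, toy_genome):
        clustered = [_to_partner("2", (5_000_000 + 300 * i, 5_000_100 + 300 * i))
                     for i in range(4)]
        step = 10_000_000 // 9
        dispersed = [_to_partner("2", (step * (2 * i + 1), step * (2 * i + 2)))
                     for i in range(4)]
        hi = translocation_score(_region("1", clustered), toy_genome)
        lo = translocation_score(_region("1", dispersed), toy_genome)
        assert hi.score > lo.score

    def test_invariant_to_partner_relabeling(self, toy_genome):
        # equal-length chromosomes: swapping partner labels preserves the score
        a = [_to_partner("2", (5_000_000, 5_001_000)), _to_partner("2", (5_002_000, 5_003_000)),
             _to_partner("3", (1_000_000, 1_001_000))]
        b = [_to_partner("3", (5_000_000, 5_001_000)), _to_partner("3", (5_002_000, 5_003_000)),
             _to_partner("2", (1_000_000, 1_001_000))]
        ra = translocation_score(_region("1", a), toy_genome)
        rb = translocation_score(_region("1", b), toy_genome)
        assert ra.score == pytest.approx(rb.score)

    def test_intrachromosomal_counts_once_per_end(self, toy_genome):
        t = TranslocationCall("1", 1000, 2000, "1", 500_000, 501_000, 1.0)
        res = translocation_score(_region("1", [t]), toy_genome)
        (p,) = res.partners
        assert p.chrom == "1" and p.count == 2
        assert len(p.breakpoints) == 4


class TestHeterozygosity:
    def test_no_loh_scores_one(self):
        assert heterozygosity_score((1, 10_000_000), [(4_000_001, 6_000_000)], []) == 1.0

    def test_loh_covering_region_scores_zero(self):
        assert heterozygosity_score((1, 10_000_000), [], [(1, 10_000_000)]) == 0.0

    def test_partial_overlap_fraction(self):
        # predicted heterozygous: 8 Mbp; LOH overlaps 2 Mbp of it -> 0.75
        score = heterozygosity_score(
            (1, 10_000_000), [(4_000_001, 6_000_000)], [(1, 2_000_000)]
        )
        assert score == pytest.approx(0.75, abs=1e-6)

    def test_cnvs_tiling_region_score_zero(self):
        assert heterozygosity_score((1, 100), [(1, 100)], []) == 0.0

    @settings(max_examples=40, derandomize=True)
    @given(st.data())
    def test_score_plus_overlap_fraction_is_one(self, data):
        region = (1, 10_000)
        ivs = st.tuples(st.integers(1, 10_000), st.integers(1, 10_000)).map(sorted).map(tuple)
        cnvs = data.draw(st.lists(ivs, max_size=5))
        lohs = data.draw(st.lists(ivs, max_size=5))
        from shatterscan import intervals

        hetero = intervals.subtract(region, cnvs)
        denom = intervals.total_length(hetero)
        score = heterozygosity_score(region, cnvs, lohs)
        if denom == 0:
            assert score == 0.0
        else:
            frac = intervals.total_length(intervals.intersect(hetero, lohs)) / denom
            assert score + frac == pytest.approx(1.0)


class TestInsertionScore:
    def test_half_of_breakpoints_matched(self):
        bps = [100, 5000, 9000, 20_000]
        ins = [105, 8995]
        assert insertion_score(bps, ins) == 0.5

    def test_window_boundary_is_inclusive(self):
        assert insertion_score([100], [110]) == 1.0
        assert insertion_score([100], [111]) == 0.0

    def test_no_insertions_or_no_breakpoints(self):
        assert insertion_score([100], []) == 0.0
        assert insertion_score([], [100]) == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(
        bps=st.lists(st.integers(1, 5000), min_size=1, max_size=50),
        ins=st.lists(st.integers(1, 5000), max_size=30),
        window=st.integers(0, 25),
    )
    def test_matches_bruteforce_pairing_oracle(self, bps, ins, window):
        oracle = sum(any(abs(b - i) <= window for i in ins) for b in bps) / len(bps)
        assert insertion_score(bps, ins, window) == pytest.approx(oracle)


class TestTP53:
    def test_user_flag_drives_score(self):
        assert tp53_score(True) == 1.0
        assert tp53_score(False) == 0.0

    def test_scan_flags_overlapping_cnv(self):
        genome = GenomeModel((("17", 81_195_210),))
        interval = ("17", 7_570_000, 7_590_000)
        cnv = CNVCall("17", 7_575_000, 7_580_000, 1, 1.0)
        assert tp53_scan([], [cnv], [], [], interval, genome) is True
        far = CNVCall("17", 1, 1000, 1, 1.0)
        assert tp53_scan([], [far], [], [], interval, genome) is False

    def test_scan_sees_all_call_types(self):
        genome = GenomeModel((("17", 81_195_210), ("1", 1_000_000)))
        interval = ("17", 7_570_000, 7_590_000)
        t = TranslocationCall("1", 1, 2, "17", 7_571_000, 7_572_000, 1.0)
        loh = LOHCall("17", 7_560_000, 7_575_000, 1.0)
        ins = InsertionCall("17", 7_589_999, 3)
        assert tp53_scan([t], [], [], [], interval, genome) is True
        assert tp53_scan([], [], [loh], [], interval, genome) is True
        assert tp53_scan([], [], [], [ins], interval, genome) is True
        assert tp53_scan([], [], [], [], interval, genome) is False


@settings(max_examples=40, derandomize=True)
@given(st.data())
def test_all_hallmark_scores_stay_in_unit_interval(data):
    """Randomized call sets never push any sub-score outside [0, 1]."""
    genome = GenomeModel(tuple((str(i), 10_000_000) for i in range(1, 13)))
    pos = st.integers(1, 10_000_000)
    iv = st.tuples(pos, pos).map(sorted)
    chrom = st.sampled_from([str(i) for i in range(1, 13)])

    translocations = []
    for _ in range(data.draw(st.integers(0, 8))):
        (s1, e1), (s2, e2) = data.draw(iv), data.draw(iv)
        translocations.append(
            TranslocationCall("1", s1, e1, data.draw(chrom), s2, e2, 1.0)
        )
    cnvs = [CNVCall("1", *data.draw(iv), data.draw(st.integers(0, 6)), 1.0)
            for _ in range(data.draw(st.integers(0, 8)))]
    lohs = [LOHCall("1", *data.draw(iv), 1.0) for _ in range(data.draw(st.integers(0, 4)))]

    region = MutatedRegion("1", 1, 10_000_000, breakpoint_count=max(1, len(cnvs)),
                           region_density=1e-6, translocations=tuple(translocations),
                           cnvs=tuple(cnvs), lohs=tuple(lohs))
    scores = [
        cnv_score(cn_oscillations(cnvs)),
        translocation_score(region, genome).score,
        heterozygosity_score((1, 10_000_000), [(c.start, c.end) for c in cnvs],
                             [(l.start, l.end) for l in lohs]),
        genome_localization_score(data.draw(st.floats(0, 10)), 1.0, 0.5),
        chromosome_localization_score(data.draw(st.integers(0, 100)), 1000, 0.01),
    ]
    assert all(0.0 <= s <= 1.0 for s in scores)
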