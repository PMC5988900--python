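import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import pwm_freq_dicts, random_genome, random_pwm
from cyclereg.io import GenomeSequence, PeakInterval
from cyclereg.motifs import (
    PWM,
    DegenerateMotif,
    PromoterWindow,
    build_pwm,
    count_peak_overlaps,
    count_sites_in_window,
    loop_accessibility,
    match_degenerate,
    promoter_window,
    reverse_complement,
    scan_genome,
    score_window,
)
from cyclereg.phases import NcRNARecord, TimeCourseProfile
from oracles import (
    brute_force_degenerate,
    brute_force_scan,
    interval_overlap_count,
    window_score,
)

FLAT8 = TimeCourseProfile(values=(1.0,) * 8)


def _record(tss, strand):
    return NcRNARecord(
        id="CCNA_R0001", tss_position=tss, strand=strand,
        category="small ncRNA", timecourse=FLAT8,
    )


class TestBuildPwm:
    def test_pure_consensus(self):
        pwm = build_pwm(["AAAA"] * 10, pseudocount=0.0)
        assert np.allclose(pwm.freqs[:, 0], 1.0)
        assert pwm.max_score == pytest.approx(2.0)

    def test_uniform_position_contributes_zero(self):
        # position 1 covered equally by all bases -> 2 + log2 0.25 = 0 for any base
        pwm = build_pwm(["AA", "CA", "GA", "TA"], pseudocount=0.0)
        assert score_window(pwm, "GA") == pytest.approx(1.0)  # (0 + 2) / 2
        assert score_window(pwm, "TA") == score_window(pwm, "CA")

    def test_pseudocount_arithmetic(self):
        pwm = build_pwm(["GG", "GA"], pseudocount=0.5)
        assert pwm.freqs[1, 0] == pytest.approx(0.375)  # A at position 2
        assert pwm.freqs[1, 2] == pytest.approx(0.375)  # G at position 2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            build_pwm(["AA", "AAA"])

    def test_zero_pseudocount_gives_minus_inf_off_consensus(self):
        pwm = build_pwm(["AA", "AA"], pseudocount=0.0)
        assert score_window(pwm, "AA") == pytest.approx(2.0)
        assert score_window(pwm, "AC") == float("-inf")


class TestScoreWindow:
    def test_consensus_scores_two_bits(self):
        pwm = build_pwm(["ACGT"] * 5, pseudocount=0.0)
        assert score_window(pwm, "ACGT") == pytest.approx(2.0)

    def test_uniform_scores_zero(self):
        pwm = PWM("uni", np.full((4, 4), 0.25))
        assert score_window(pwm, "TTTT") == pytest.approx(0.0)

    def test_085_consensus_and_mismatch(self):
        # f(consensus)=0.85, others 0.05; frozen from direct evaluation of
        # the scoring formula (cross-checked with the brute-force oracle)
        freqs = np.full((3, 4), 0.05)
        freqs[:, 0] = 0.85
        pwm = PWM("p85", freqs)
        assert score_window(pwm, "AAA") == pytest.approx(2 + math.log2(0.85), abs=1e-4)
        assert score_window(pwm, "AAA") == pytest.approx(1.76553, abs=1e-4)
        s_mm = score_window(pwm, "ACA")
        assert s_mm == pytest.approx(0.40305, abs=1e-4)
        assert s_mm == pytest.approx(window_score(pwm_freq_dicts(pwm), "ACA"))

    def test_length_mismatch_rejected(self, sharp_pwm):
        with pytest.raises(ValueError, match="length"):
            score_window(sharp_pwm, "ACGT")

    def test_n_unscoreable(self, sharp_pwm):
        with pytest.raises(ValueError, match="N"):
            score_window(sharp_pwm, "TTAACCATNG")


class TestScanGenome:
    def test_planted_consensus_recovered(self, rng, sharp_pwm):
        g0 = random_genome(rng, 1000)
        seq = g0.sequence[:500] + sharp_pwm.consensus() + g0.sequence[510:]
        g = GenomeSequence("chr", seq)
        hits = scan_genome(sharp_pwm, g, rel_threshold=0.6)
        oracle = brute_force_scan(pwm_freq_dicts(sharp_pwm), seq, True, 0.6)
        assert {(h.start, h.strand) for h in hits} == oracle
        assert any(h.start == 501 and h.relative_score == pytest.approx(1.0) for h in hits)

    def test_exact_threshold_boundary(self):
        # exact-binary frequencies: consensus column f=1/2 contributes 1 bit,
        # f=1/4 contributes 0, f=1/8 contributes -1; S_max = 1
        col = np.array([0.5, 0.25, 0.125, 0.125])
        pwm = PWM("exact", np.tile(col, (5, 1)))
        assert pwm.max_score == pytest.approx(1.0)
        g = GenomeSequence("chr", "AAACCGGGGGGGGGG", circular=False)
        # window AAACC scores (1+1+1+0+0)/5 = 0.6 exactly -> retained at 0.6
        hits = scan_genome(pwm, g, rel_threshold=0.6, both_strands=False)
        assert any(h.start == 1 and h.relative_score == pytest.approx(0.6) for h in hits)
        # just above the same window's score -> discarded
        hits_above = scan_genome(pwm, g, rel_threshold=np.nextafter(0.6, 1), both_strands=False)
        assert not any(h.start == 1 for h in hits_above)
        # a window at 0.4 of max fails the 0.6 cut: AACCG = (1+1+0+0+-1)/5
        assert not any(h.start == 2 for h in hits)

    def test_circular_wraparound_hit(self, sharp_pwm):
        cons = sharp_pwm.consensus()  # length 10
        # plant so the site starts at position 18 of a 20-mer and wraps
        seq = cons[3:] + "AAAAAAAAAA" + cons[:3]
        g = GenomeSequence("chr", seq, circular=True)
        hits = scan_genome(sharp_pwm, g, rel_threshold=0.9)
        wrapped = [h for h in hits if h.start == 18]
        assert len(wrapped) == 1 and wrapped[0].end == 7
        assert wrapped[0].matched_sequence == cons

    def test_linear_genome_has_no_wrapped_hits(self, rng):
        pwm = random_pwm(rng, 6)
        g = random_genome(rng, 300, name="lin")
        g_lin = GenomeSequence(g.name, g.sequence, circular=False)
        hits = scan_genome(pwm, g_lin, rel_threshold=0.0)
        assert max(h.start for h in hits) <= len(g_lin) - pwm.length + 1

    def test_uniform_pwm_rejected(self):
        with pytest.raises(ValueError, match="degenerate PWM"):
            scan_genome(PWM("uni", np.full((4, 4), 0.25)), GenomeSequence("c", "ACGTACGT"))

    def test_n_windows_skipped(self, sharp_pwm):
        g = GenomeSequence("chr", sharp_pwm.consensus() + "N" * 10 + sharp_pwm.consensus(),
                           circular=False)
        hits = scan_genome(sharp_pwm, g, rel_threshold=0.9)
        assert {h.start for h in hits if h.strand == "+"} == {1, 21}

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("circular", [True, False])
    def test_matches_brute_force_oracle(self, seed, circular):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(4, 9))
        pwm = random_pwm(rng, L)
        g = random_genome(rng, int(rng.integers(200, 1200)))
        g = GenomeSequence(g.name, g.sequence, circular=circular)
        threshold = float(rng.uniform(0.3, 0.8))
        hits = scan_genome(pwm, g, rel_threshold=threshold)
        oracle = brute_force_scan(pwm_freq_dicts(pwm), g.sequence, circular, threshold)
        assert {(h.start, h.strand) for h in hits} == oracle

    @pytest.mark.parametrize("seed", range(4))
    def test_score_bound_and_strand_symmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        pwm = random_pwm(rng, 6)
        g = random_genome(rng, 500)
        hits = scan_genome(pwm, g, rel_threshold=0.4)
        assert all(h.raw_score <= pwm.max_score + 1e-12 for h in hits)
        assert all(h.relative_score <= 1 + 1e-12 for h in hits)
        # scanning the reverse-complement genome with the same PWM mirrors hits:
        # a hit [s, e] maps to a hit starting at n - e + 1 on the other strand
        g_rc = GenomeSequence("rc", reverse_complement(g.sequence))
        hits_rc = scan_genome(pwm, g_rc, rel_threshold=0.4)
        n = len(g)
        got = {(h.start, h.strand) for h in hits_rc}
        expect = {
            ((n - h.end) % n + 1, "-" if h.strand == "+" else "+") for h in hits
        }
        assert got == expect


class TestMatchDegenerate:
    def test_single_site(self):
        g = GenomeSequence("c", "GAATC", circular=False)
        (hit,) = match_degenerate("GANTC", g)
        assert hit.start == 1 and hit.relative_score == 1.0

    def test_two_sites_by_expansion(self):
        g = GenomeSequence("c", "GACTCGAGTC", circular=False)
        hits = match_degenerate("GANTC", g)
        assert [h.start for h in hits] == [1, 6]

    def test_palindrome_reported_once_per_duplex(self):
        g = GenomeSequence("c", "GAATC", circular=False)
        assert len(match_degenerate("GANTC", g, both_strands=True)) == 1
        assert DegenerateMotif("GANTC").is_palindromic()

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            DegenerateMotif("GAXTC")

    @pytest.mark.parametrize("pattern", ["GANTC", "TTGACW", "RYN"])
    @pytest.mark.parametrize("circular", [True, False])
    def test_matches_brute_force_oracle(self, rng, pattern, circular):
        g = random_genome(rng, 10_000)
        g = GenomeSequence(g.name, g.sequence, circular=circular)
        hits = match_degenerate(pattern, g)
        oracle = brute_force_degenerate(pattern, g.sequence, circular)
        assert {(h.start, h.strand) for h in hits} == oracle

    def test_palindrome_strand_count_symmetry(self, rng):
        g = random_genome(rng, 20_000)
        plus_only = match_degenerate("GANTC", g, both_strands=False)
        both = match_degenerate("GANTC", g, both_strands=True)
        assert len(plus_only) == len(both)
        assert {(h.start, h.end) for h in plus_only} == {(h.start, h.end) for h in both}


class TestPromoterWindow:
    def test_plus_strand_layout(self):
        w = promoter_window(_record(938932, "+"))
        assert (w.start, w.end) == (938832, 938982)

    def test_minus_strand_mirrored(self):
        w = promoter_window(_record(757263, "-"))
        assert (w.start, w.end) == (757213, 757363)

    def test_circular_wrap_near_origin(self):
        w = promoter_window(_record(50, "+"), genome_length=1000)
        assert (w.start, w.end) == (950, 100)
        assert (w.end - w.start) % 1000 + 1 == 151

    def test_nonpositive_tss_rejected(self):
        with pytest.raises(ValueError, match="nonpositive TSS"):
            promoter_window(_record(1, "+").__class__(
                id="CCNA_R0001", tss_position=0, strand="+",
                category="small ncRNA", timecourse=FLAT8))

    @given(tss=st.integers(min_value=1, max_value=4_000_000),
           strand=st.sampled_from(["+", "-"]))
    @settings(max_examples=100, deadline=None)
    def test_windows_always_151nt(self, tss, strand):
        n = 4_000_000
        w = promoter_window(_record(tss, strand), genome_length=n)
        assert (w.end - w.start) % n + 1 == 151
        off_tss = (tss - w.start) % n
        assert off_tss == (100 if strand == "+" else 50)


class TestWindowCounts:
    WIN = PromoterWindow("x", "chr", 150, 300, "+", 250)

    def _hit(self, s, e):
        from cyclereg.motifs import MotifHit

        return MotifHit("m", s, e, "+", 1.0, 1.0, "")

    def test_containment_excludes_straddlers(self):
        hits = [self._hit(160, 169), self._hit(200, 209), self._hit(291, 300),
                self._hit(295, 304)]
        assert count_sites_in_window(hits, self.WIN) == 3

    def test_empty_hits(self):
        assert count_sites_in_window([], self.WIN) == 0

    def test_wrapped_window_containment(self):
        win = PromoterWindow("x", "chr", 950, 100, "+", 50)
        hits = [self._hit(960, 969), self._hit(995, 4), self._hit(95, 104), self._hit(5, 14)]
        assert count_sites_in_window(hits, win, genome_length=1000) == 3

    def test_peak_any_overlap(self):
        assert count_peak_overlaps([PeakInterval("chr", 100, 200)], self.WIN) == 1
        assert count_peak_overlaps([PeakInterval("chr", 100, 149)], self.WIN) == 0

    def test_random_counts_match_oracle(self, rng):
        peaks = [
            PeakInterval("chr", int(s), int(s + w))
            for s, w in zip(rng.integers(1, 5000, 100), rng.integers(1, 300, 100))
        ]
        for _ in range(10):
            s = int(rng.integers(1, 4800))
            win = PromoterWindow("x", "chr", s, s + 150, "+", s + 100)
            expected = interval_overlap_count(
                [(p.start, p.end) for p in peaks], (win.start, win.end)
            )
            assert count_peak_overlaps(peaks, win) == expected


class TestLoopAccessibility:
    @pytest.mark.parametrize(
        "db,interval,expected",
        [
            ("((((....))))", (5, 8), 1.0),
            ("((((....))))", (1, 4), 0.0),
            ("..((..))..", (1, 10), 0.6),
        ],
    )
    def test_fractions(self, db, interval, expected):
        assert loop_accessibility(db, interval) == pytest.approx(expected)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            loop_accessibility("((..", (1, 4))
        with pytest.raises(ValueError, match="unbalanced"):
            loop_accessibility("..))((", (1, 6))

    def test_interval_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            loop_accessibility("....", (2, 5))
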