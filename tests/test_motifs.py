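import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from exapt.errors import ParameterError
from exapt.motifs import (
    BUILTIN_MOTIFS,
    MotifDefinition,
    MotifHit,
    density_profile,
    discriminative_kmer_enrichment,
    merge_hits,
    motif_gain_fold_change,
    nearest_motif_spacing,
    reverse_complement,
    scan_iupac,
    threshold_scan,
)
from exapt.intervals import GenomeInterval

IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "Y": "[CT]",
    "K": "[GT]", "M": "[AC]", "S": "[CG]", "W": "[AT]", "B": "[CGT]",
    "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def brute_scan_positions(seq, iupac):
    """Window-by-window regex oracle (plus strand), overlapping matches."""
    pattern = re.compile("(?=" + "".join(IUPAC_RE[c] for c in iupac) + ")")
    return [m.start() for m in pattern.finditer(seq)]


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mk_hit(start, length=6, score=1.0, chrom="seq", strand="+", top=True):
    return MotifHit(
        interval=GenomeInterval(chrom, start, start + length, strand=strand),
        strand=strand, score=score, motif="m", is_top_score=top,
    )


class TestScanIupac:
    def test_palindromic_motif_self_hit_collapsed_to_plus(self):
        hits = scan_iupac("CACGTG", BUILTIN_MOTIFS["E-Box-canonical"])
        assert len(hits) == 1
        assert hits[0].strand == "+" and hits[0].interval.start == 0
        assert hits[0].is_top_score

    def test_degenerate_ebox_reports_both_strand_hits(self):
        # CACRTG is not a palindromic pattern, so the palindromic *sequence*
        # CACGTG matches it once per strand at the same window
        hits = scan_iupac("CACGTG", BUILTIN_MOTIFS["E-Box"])
        assert {(h.interval.start, h.strand) for h in hits} == {(0, "+"), (0, "-")}

    def test_degenerate_position_matches(self):
        assert len(scan_iupac("CACATG", BUILTIN_MOTIFS["E-Box"])) == 1
        assert scan_iupac("CACATG", BUILTIN_MOTIFS["E-Box-canonical"]) == []

    def test_n_never_matches(self):
        assert scan_iupac("CACNTG", BUILTIN_MOTIFS["E-Box"]) == []

    def test_score_is_uniform_column_log_odds(self):
        (hit,) = scan_iupac("CACATG", BUILTIN_MOTIFS["E-Box"])
        # five fixed columns contribute 2 bits each, the R column 1 bit
        assert hit.score == pytest.approx(11.0)

    def test_fixed_sequence_matches_regex_oracle(self):
        seq = "AGGTCAAGGTCATTTGACCTTTAGGTCNAGGKCATGACCTAGGTCAGTACAGGTCATGAC"
        motif = BUILTIN_MOTIFS["RORE"]
        got = {(h.interval.start, h.strand) for h in scan_iupac(seq, motif)}
        want = {(p, "+") for p in brute_scan_positions(seq, motif.iupac)}
        rc = reverse_complement(motif.iupac)
        want |= {(p, "-") for p in brute_scan_positions(seq, rc)}
        assert got == want

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_random_sequences_match_regex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 2000)
        for name in ("E-Box", "RORE", "D-Box"):
            motif = BUILTIN_MOTIFS[name]
            got = {(h.interval.start, h.strand) for h in scan_iupac(seq, motif)}
            want = {(p, "+") for p in brute_scan_positions(seq, motif.iupac)}
            for p in brute_scan_positions(seq, reverse_complement(motif.iupac)):
                if motif.is_palindromic and (p, "+") in want:
                    continue
                want.add((p, "-"))
            assert got == want

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 500)
        motif = BUILTIN_MOTIFS["RORE"]
        fwd = scan_iupac(seq, motif)
        rev = scan_iupac(reverse_complement(seq), motif)
        n = len(seq)
        mirrored = {
            (n - h.interval.end, "+" if h.strand == "-" else "-") for h in rev
        }
        assert {(h.interval.start, h.strand) for h in fwd} == mirrored

    def test_invalid_motif_letter_rejected(self):
        with pytest.raises(ParameterError):
            MotifDefinition("bad", "CACXTG")


class TestThresholdScan:
    def test_vacuous_threshold_reports_every_window(self):
        seq = "ACGTACGTAC"
        hits = threshold_scan(seq, BUILTIN_MOTIFS["E-Box-canonical"], p_threshold=1.0)
        # palindromic motif: one (plus-strand) report per window
        assert len(hits) == len(seq) - 6 + 1

    def test_equals_exact_scan_at_max_stringency(self, rng):
        seq = random_dna(rng, 5000)
        for name in ("E-Box", "RORE", "D-Box"):
            motif = BUILTIN_MOTIFS[name]
            exact = {(h.interval.start, h.strand) for h in scan_iupac(seq, motif)}
            thr = {
                (h.interval.start, h.strand)
                for h in threshold_scan(seq, motif, p_threshold=motif.match_probability)
            }
            assert exact == thr

    def test_hit_density_matches_closed_form(self, rng):
        n = 1_000_000
        seq = random_dna(rng, n)
        windows = n - 6 + 1
        # palindromic canonical E-Box: collapsed hits occur at rate (1/4)^6
        p_pal = (1 / 4) ** 6
        hits = threshold_scan(seq, BUILTIN_MOTIFS["E-Box-canonical"], p_threshold=0.01)
        se = np.sqrt(windows * p_pal * (1 - p_pal))
        assert abs(len(hits) - windows * p_pal) < 3 * se
        # non-palindromic optimal RORE: both strands contribute, rate 2*(1/4)^6
        p2 = 2 * (1 / 4) ** 6
        hits2 = threshold_scan(seq, BUILTIN_MOTIFS["RORE-optimal"], p_threshold=0.01)
        se2 = np.sqrt(windows * p2 * (1 - p2))
        assert abs(len(hits2) - windows * p2) < 3 * se2

    def test_too_long_motif_rejected(self):
        with pytest.raises(ParameterError):
            threshold_scan("ACGT" * 10, MotifDefinition("long", "A" * 17))


class TestMergeHits:
    def test_disjoint_hits_untouched(self):
        merged = merge_hits([mk_hit(0, score=4.0), mk_hit(10, score=8.0)])
        assert [(m.interval.start, m.interval.end, m.score) for m in merged] == [
            (0, 6, 4.0), (10, 16, 8.0)
        ]

    def test_overlapping_pair_union_and_mean(self):
        merged = merge_hits([mk_hit(0, score=4.0), mk_hit(3, score=8.0)])
        (m,) = merged
        assert (m.interval.start, m.interval.end) == (0, 9)
        assert m.score == pytest.approx(6.0)
        assert m.n_members == 2

    def test_transitive_chain_collapses(self):
        merged = merge_hits([mk_hit(0), mk_hit(4), mk_hit(8)])
        (m,) = merged
        assert m.n_members == 3 and (m.interval.start, m.interval.end) == (0, 14)

    def test_output_disjoint_and_members_conserved(self, rng):
        hits = [mk_hit(int(rng.integers(0, 500))) for _ in range(100)]
        merged = merge_hits(hits)
        assert sum(m.n_members for m in merged) == len(hits)
        ordered = sorted(merged, key=lambda m: m.interval.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.interval.end <= b.interval.start


class TestDensityProfile:
    def region(self, center, strand="."):
        return GenomeInterval("seq", center - 50, center + 50, strand=strand)

    def test_no_hits_all_zero(self):
        prof = density_profile([self.region(500)], [], flank=100)
        assert prof.values.sum() == 0 and len(prof.values) == 201

    def test_single_central_hit_delta(self):
        (m,) = merge_hits([mk_hit(497, score=5.0)])
        prof = density_profile([self.region(500)], [m], flank=100)
        assert prof.values[100] == pytest.approx(5.0)  # offset 0 covered
        assert prof.values[:95].sum() == 0

    def test_mean_is_linear_in_regions(self):
        (m,) = merge_hits([mk_hit(497, score=5.0)])
        one = density_profile([self.region(500)], [m], flank=100)
        two = density_profile([self.region(500), self.region(5000)], [m], flank=100)
        np.testing.assert_allclose(two.values, one.values / 2)

    def test_invariant_under_region_order(self):
        hits = merge_hits([mk_hit(497, score=5.0), mk_hit(5010, score=2.0)])
        regions = [self.region(500), self.region(5000)]
        a = density_profile(regions, hits, flank=100)
        b = density_profile(regions[::-1], hits, flank=100)
        np.testing.assert_allclose(a.values, b.values)

    def test_minus_strand_region_flipped(self):
        (m,) = merge_hits([mk_hit(520, score=3.0)])
        fwd = density_profile([self.region(500, "+")], [m], flank=100)
        rev = density_profile([self.region(500, "-")], [m], flank=100)
        np.testing.assert_allclose(rev.values, fwd.values[::-1])


class TestNearestMotifSpacing:
    def test_six_nt_gap_gives_twelve(self):
        distances = nearest_motif_spacing([mk_hit(0), mk_hit(12)])
        assert distances == [12, 12]

    def test_single_hit_contributes_nothing(self):
        assert nearest_motif_spacing([mk_hit(3)]) == []

    def test_three_equally_spaced(self):
        distances = nearest_motif_spacing([mk_hit(0), mk_hit(12), mk_hit(24)])
        assert distances == [12, 12, 12]

    def test_overlapping_hits_skipped(self):
        distances = nearest_motif_spacing([mk_hit(0), mk_hit(3), mk_hit(20)])
        assert distances == [20, 17, 17]

    def test_top_score_filter(self):
        hits = [mk_hit(0), mk_hit(12, top=False), mk_hit(40)]
        assert nearest_motif_spacing(hits, top_score_only=True) == [40, 40]


class TestKmerEnrichment:
    def test_perfect_separator_ranked_first(self, rng):
        fg = ["TT" + "CACGTG" + random_dna(rng, 10) for _ in range(20)]
        bg = [random_dna(rng, 18).replace("CACGTG", "AAAAAA") for _ in range(20)]
        table = discriminative_kmer_enrichment(fg, bg, k=6)
        row = table.set_index("kmer").loc["CACGTG"]
        # perfect separator: fully discriminative and tied for the minimal p
        # (k-mers spanning the constant flank separate perfectly too)
        assert row.fg_fraction == 1.0 and row.bg_fraction == 0.0
        assert row.p == table.p.min()

    def test_identical_sets_are_null(self, rng):
        seqs = [random_dna(rng, 30) for _ in range(15)]
        table = discriminative_kmer_enrichment(seqs, seqs, k=5)
        assert (table.fold == 1.0).all()
        assert (table.p > 0.2).all()

    def test_planted_kmer_fold_and_p(self, rng):
        planted = "GATTAC"
        fg = [
            (planted if i < 50 else random_dna(rng, 6)) + random_dna(rng, 24)
            for i in range(100)
        ]
        bg = [
            (planted if i < 5 else random_dna(rng, 6)) + random_dna(rng, 24)
            for i in range(100)
        ]
        table = discriminative_kmer_enrichment(fg, bg, k=6).set_index("kmer")
        row = table.loc[min(planted, reverse_complement(planted))]
        assert row.fold > 5
        assert row.p < 1e-6
        # p agrees with the exact hypergeometric tail
        fg_n = int(round(row.fg_fraction * 100))
        bg_n = int(round(row.bg_fraction * 100))
        expected = stats.hypergeom.sf(fg_n - 1, 200, fg_n + bg_n, 100)
        assert row.p == pytest.approx(expected, rel=1e-9)

    def test_parameter_errors(self, rng):
        with pytest.raises(ParameterError):
            discriminative_kmer_enrichment([], ["ACGT"], k=2)
        with pytest.raises(ParameterError):
            discriminative_kmer_enrichment(["ACGT"], ["ACG"], k=4)


class TestMotifGain:
    def test_identity_fold_one(self, rng):
        seqs = ["AA" + "CACGTG" + random_dna(rng, 8) for _ in range(10)]
        out = motif_gain_fold_change(seqs, seqs, BUILTIN_MOTIFS["E-Box-canonical"])
        assert out.fold == 1.0 and not out.undefined_denominator

    def test_ten_fold(self):
        bound = ["TT" + "CACGTG" + "TT"] * 10
        unbound = ["TT" + "CACGTG" + "TT"] + ["TTTTTTTTTT"] * 9
        out = motif_gain_fold_change(bound, unbound, BUILTIN_MOTIFS["E-Box-canonical"])
        assert out.fold == pytest.approx(10.0)

    def test_zero_denominator_flagged(self):
        out = motif_gain_fold_change(
            ["CACGTG"], ["TTTTTT"], BUILTIN_MOTIFS["E-Box-canonical"]
        )
        assert out.fold == float("inf") and out.undefined_denominator
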