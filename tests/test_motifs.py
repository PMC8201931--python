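"""DRACH scanning, pairwise alignment, motif gain/loss classification,
strand-bias chi-square and divergence statistics, against independent
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    best_alignment_score_enumerated,
    drach_positions,
    drach_positions_antisense,
    rc,
    recount_motif_changes,
)
from pseudom6a.motifs import (
    alignment_from_gapped,
    classify_motif_changes,
    divergence_level_correlation,
    global_align,
    is_drach,
    revcomp,
    scan_drach,
    sequence_divergence,
    strand_bias_test,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestScanDrach:
    def test_sense_example(self):
        sites = scan_drach("TGGACTA", "sense")
        assert [(s.pos, s.kmer) for s in sites] == [(3, "GGACT")]

    def test_antisense_example_empty(self):
        assert scan_drach("TGGACTA", "antisense") == []

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(dna)
    def test_equals_exhaustive_pattern_check(self, seq):
        assert [s.pos for s in scan_drach(seq, "sense")] == drach_positions(seq)
        assert sorted(s.pos for s in scan_drach(seq, "antisense")) == (
            drach_positions_antisense(seq)
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna)
    def test_revcomp_symmetry(self, seq):
        """Antisense scan == coordinate-mapped sense scan of the revcomp."""
        anti = sorted(s.pos for s in scan_drach(seq, "antisense"))
        mapped = sorted(
            len(seq) - 1 - s.pos for s in scan_drach(revcomp(seq), "sense")
        )
        assert anti == mapped

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError):
            scan_drach("ACGT", "reverse")


class TestGlobalAlign:
    def test_identical_sequences_gapless(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.aligned_pseudo == aln.aligned_cognate == "ACGTACGT"
        assert sequence_divergence(aln) == 0.0
        assert aln.score == 16.0

    def test_single_gap_opposite_g(self):
        aln = global_align("ACGT", "ACT")
        assert aln.aligned_pseudo == "ACGT"
        assert aln.aligned_cognate in ("AC-T",)
        assert aln.score == 3 * 2 - 5

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=6),
           st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_score_optimal_vs_enumeration_short(self, a, b):
        assert global_align(a, b).score == best_alignment_score_enumerated(a, b)

    def test_score_optimal_vs_enumeration_8nt(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            a = "".join(rng.choice(list("ACGT"), 8))
            b = "".join(rng.choice(list("ACGT"), 8))
            assert global_align(a, b).score == best_alignment_score_enumerated(a, b)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(dna, dna)
    def test_ungapping_round_trip(self, a, b):
        aln = global_align(a, b)
        assert aln.pseudo_seq == a
        assert aln.cognate_seq == b
        assert len(aln.aligned_pseudo) == len(aln.aligned_cognate)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")


class TestClassifyMotifChanges:
    def test_single_disruption_is_gained(self):
        aln = alignment_from_gapped("p", "GGACT", "GGGCT")
        rec = classify_motif_changes(aln, [(0, 5)], [(0, 5)], "sense")
        assert (rec.gained, rec.lost, rec.shared) == (1, 0, 0)

    def test_identical_sequences_all_shared(self):
        seq = "TTGGACTTAAGGACAA"
        aln = alignment_from_gapped("p", seq, seq)
        rec = classify_motif_changes(aln, [(0, len(seq))], [(0, len(seq))], "sense")
        assert rec.gained == rec.lost == 0
        assert rec.shared == len(drach_positions(seq))

    def test_region_restriction(self):
        aln = alignment_from_gapped("p", "GGACT", "GGGCT")
        # peak misses the central A (position 2): motif not counted
        rec = classify_motif_changes(aln, [(0, 2)], [(0, 2)], "sense")
        assert (rec.gained, rec.lost, rec.shared) == (0, 0, 0)

    def test_union_of_either_genes_peaks(self):
        aln = alignment_from_gapped("p", "GGACT", "GGGCT")
        # only the cognate has a peak: region still covers the columns
        rec = classify_motif_changes(aln, [], [(0, 5)], "sense")
        assert rec.gained == 1

    def test_gap_spanning_motifs_tallied_separately(self):
        # cognate has a deletion inside the pseudogene's motif
        aln = alignment_from_gapped("p", "TTGGACTTT", "TTGG-CTTT")
        rec = classify_motif_changes(aln, [(0, 9)], [(0, 8)], "sense")
        assert rec.gained == 0 and rec.gap_spanning == 1

    def test_peaks_out_of_range_rejected(self):
        aln = alignment_from_gapped("p", "GGACT", "GGGCT")
        with pytest.raises(ValueError):
            classify_motif_changes(aln, [(0, 9)], [], "sense")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_column_walk_recount(self, seed):
        """Random gapped pairs: counts equal an independent recount."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(30, 120))
        p = rng.choice(list("ACGT"), L).tolist()
        c = list(p)
        for _ in range(int(rng.integers(0, L // 3))):
            c[int(rng.integers(0, L))] = str(rng.choice(list("ACGT")))
        # sprinkle a few gaps on either side (no all-gap columns)
        for _ in range(int(rng.integers(0, 4))):
            j = int(rng.integers(0, len(p)))
            if p[j] != "-" and c[j] != "-":
                (p if rng.random() < 0.5 else c)[j] = "-"
        ap, ac = "".join(p), "".join(c)
        aln = alignment_from_gapped("p", ap, ac)
        lp, lc = len(aln.pseudo_seq), len(aln.cognate_seq)
        peaks_p = [(0, max(1, lp // 2))] if lp else []
        peaks_c = [(lc // 3, lc)] if lc > lc // 3 else []
        for strand in ("sense", "antisense"):
            rec = classify_motif_changes(aln, peaks_p, peaks_c, strand)
            want = recount_motif_changes(ap, ac, peaks_p, peaks_c, strand)
            got = {"gained": rec.gained, "lost": rec.lost,
                   "shared": rec.shared, "gap_spanning": rec.gap_spanning}
            assert got == want

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_strand_duality_under_reverse_complement(self, seed):
        """Reverse-complementing both sequences swaps sense and antisense."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(20, 80))
        a = "".join(rng.choice(list("ACGT"), L))
        b = list(a)
        for _ in range(L // 5):
            b[int(rng.integers(0, L))] = str(rng.choice(list("ACGT")))
        b = "".join(b)
        aln = alignment_from_gapped("p", a, b)
        aln_rc = alignment_from_gapped("p", rc(a), rc(b))
        peaks = [(0, L)]
        for strand, other in (("sense", "antisense"), ("antisense", "sense")):
            r1 = classify_motif_changes(aln, peaks, peaks, strand)
            r2 = classify_motif_changes(aln_rc, peaks, peaks, other)
            assert (r1.gained, r1.lost, r1.shared) == (r2.gained, r2.lost, r2.shared)


class TestStrandBiasTest:
    def test_identical_proportions_null(self):
        res = strand_bias_test(10, 100, 10, 100)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_reconstructed_peak_presence_table(self):
        res = strand_bias_test(145, 223, 116, 223)
        assert res.p_yates == pytest.approx(0.007, abs=0.001)
        assert res.p == pytest.approx(0.0053, abs=0.001)

    def test_agrees_with_permutation_oracle(self):
        """Uncorrected chi-square p matches a label-permutation null within
        Monte-Carlo error on a moderate table."""
        a_hit, a_n, b_hit, b_n = 30, 100, 45, 100
        res = strand_bias_test(a_hit, a_n, b_hit, b_n)
        rng = np.random.default_rng(8)
        pool = np.array([1] * (a_hit + b_hit) + [0] * (a_n + b_n - a_hit - b_hit))
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            rng.shuffle(pool)
            pa = pool[:a_n].sum()
            pb = pool[a_n:].sum()
            r = strand_bias_test(int(pa), a_n, int(pb), b_n)
            if r.chi2 >= res.chi2 - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert res.p == pytest.approx(p_perm, abs=0.02)

    def test_degenerate_and_invalid_tables(self):
        res = strand_bias_test(0, 10, 0, 10)
        assert res.p == 1.0
        with pytest.raises(ValueError):
            strand_bias_test(11, 10, 0, 10)
        with pytest.raises(ValueError):
            strand_bias_test(0, 0, 0, 10)

    def test_low_expected_flagged(self):
        assert strand_bias_test(1, 2, 0, 2).low_expected


class TestDivergence:
    def test_examples(self):
        assert sequence_divergence(alignment_from_gapped("p", "ACGT", "ACGA")) == 0.25
        assert sequence_divergence(alignment_from_gapped("p", "ACGT", "ACGT")) == 0.0

    def test_gap_columns_excluded(self):
        aln = alignment_from_gapped("p", "ACGT-", "AC-TG")
        # gap-free columns: A/A, C/C, T/T -> divergence 0
        assert sequence_divergence(aln) == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(dna, dna)
    def test_matches_column_walk(self, a, b):
        aln = global_align(a, b)
        mism = total = 0
        for x, y in zip(aln.aligned_pseudo, aln.aligned_cognate):
            if x != "-" and y != "-":
                total += 1
                mism += x != y
        if total == 0:
            with pytest.raises(ValueError):
                sequence_divergence(aln)
        else:
            assert sequence_divergence(aln) == mism / total


class TestDivergenceLevelCorrelation:
    def test_perfect_line(self):
        x = [0.1, 0.2, 0.3, 0.4]
        r, p = divergence_level_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_generative_cohort_positive(self, report):
        dl = report.headline["motifs"]["divergence_level"]
        assert dl["processed"]["r"] > 0
        assert dl["processed"]["p"] < 0.05

    def test_permuted_pairing_is_null(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 0.3, 100)
        y = 0.1 + 2.0 * x + rng.normal(0, 0.05, 100)
        n_sig = 0
        for _ in range(50):
            yp = rng.permutation(y)
            _, p = divergence_level_correlation(x, yp)
            n_sig += p < 0.05
        assert n_sig <= 10  # ~5% expected under the permuted null

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            divergence_level_correlation([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(ValueError):
            divergence_level_correlation([0.1] * 5, [0.1, 0.2, 0.3, 0.4, 0.5])
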