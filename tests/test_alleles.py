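import math

import numpy as np
import pytest

from svk.alleles import (
    SSIII_DOMAINS,
    AlignmentResult,
    DomainMap,
    Variant,
    align_global,
    apply_variants,
    assign_domains,
    call_variants,
    classify_effects,
    compare_alleles,
    find_longest_orf,
    summarize_alleles,
    translate_cds,
)
from svk.io import SequenceRecord
from svk.simulate import AlleleSimSpec, simulate_allele_pair

from tests.conftest import random_dna


def nw_affine_score(a, b, match=1.0, mismatch=-2.0, gap_open=-6.0, gap_extend=-1.0):
    """Brute-force affine-gap global alignment score (length-L gap costs
    open + L*extend).  Independent three-matrix DP oracle."""
    n, m = len(a), len(b)
    neg = -math.inf
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open + gap_extend, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_extend, Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def rescore(aln: AlignmentResult, match=1.0, mismatch=-2.0, gap_open=-6.0, gap_extend=-1.0):
    """Recompute the score of a gapped alignment from its columns."""
    score = 0.0
    in_gap = None
    for r, a in zip(aln.gapped_ref, aln.gapped_alt):
        if r == "-" or a == "-":
            which = "ref" if r == "-" else "alt"
            if in_gap != which:
                score += gap_open
            score += gap_extend
            in_gap = which
        else:
            score += match if r == a else mismatch
            in_gap = None
    return score


def rec(seq, seq_id="s"):
    return SequenceRecord(seq_id, seq)


class TestAlignGlobal:
    def test_identical_sequences(self):
        aln = align_global(rec("ACGTACGTAC"), rec("ACGTACGTAC"))
        assert aln.gapped_ref == aln.gapped_alt == "ACGTACGTAC"
        assert aln.score == 10.0

    def test_single_mismatch_at_position_4(self):
        aln = align_global(rec("ACGTACGT"), rec("ACGAACGT"))
        assert aln.gapped_ref == "ACGTACGT"
        assert aln.gapped_alt == "ACGAACGT"
        mismatch_cols = [
            i for i, (r, a) in enumerate(zip(aln.gapped_ref, aln.gapped_alt)) if r != a
        ]
        assert [aln.ref_coord_map[i] for i in mismatch_cols] == [4]

    def test_three_column_gap_run(self):
        ref = rec("AAACGATTTCCCGGGACG")
        alt = rec("AAACGACCCGGGACG")
        aln = align_global(ref, alt)
        gap_runs = [c for c in aln.gapped_alt.split("C") if "-" in c]
        assert aln.gapped_alt.count("-") == 3
        assert "---" in aln.gapped_alt

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            SequenceRecord("x", "")

    def test_length_ratio_guard(self):
        with pytest.raises(ValueError, match="20%"):
            align_global(rec("ACGTACGTACGT"), rec("ACGTACG"))

    def test_score_matches_bruteforce_oracle(self, rng):
        for _ in range(150):
            n = int(rng.integers(4, 11))
            m = int(rng.integers(max(4, int(n * 0.8)), min(10, int(n * 1.25)) + 1))
            a, b = random_dna(rng, n), random_dna(rng, m)
            if min(n, m) < 0.8 * max(n, m):
                continue
            aln = align_global(rec(a), rec(b))
            assert aln.score == pytest.approx(nw_affine_score(a, b))
            # the emitted (left-normalized) alignment must still achieve it
            assert rescore(aln) == pytest.approx(aln.score)
            assert aln.ref == a and aln.alt == b

    def test_leftmost_gap_normalization(self):
        # deletion inside a homopolymer must sit at the leftmost position
        ref = rec("GGCAAAAATCCGGCCGGTT")
        alt = rec("GGCAAAATCCGGCCGGTT")
        aln = align_global(ref, alt)
        first_gap = aln.gapped_alt.index("-")
        assert aln.ref_coord_map[first_gap] == 4  # first A of the run

    def test_coord_map_strictly_increasing_on_ref_columns(self, rng):
        ref = rec(random_dna(rng, 60))
        alt_seq = ref.residues[:20] + ref.residues[26:]
        aln = align_global(ref, rec(alt_seq))
        positions = [
            p for p, r in zip(aln.ref_coord_map, aln.gapped_ref) if r != "-"
        ]
        assert positions == sorted(set(positions))
        assert positions[-1] == 60


class TestCallVariants:
    def test_identical_gives_empty(self):
        aln = align_global(rec("ACGTACGTAC"), rec("ACGTACGTAC"))
        assert call_variants(aln) == []

    def test_snp_positions_sorted(self):
        aln = align_global(rec("ACGTACGTACGT"), rec("ACGAACGTACGA"))
        variants = call_variants(aln)
        assert [v.ref_pos for v in variants] == [4, 12]
        assert all(v.kind == "SNP" for v in variants)

    def test_simulated_truth_recovered(self):
        spec = AlleleSimSpec(length=300, n_snps=4, n_silent=3, seed=7)
        ref, alt, truth = simulate_allele_pair(spec)
        called = call_variants(align_global(ref, alt))
        assert [(v.ref_pos, v.ref_allele, v.alt_allele, v.kind) for v in called] == [
            (v.ref_pos, v.ref_allele, v.alt_allele, v.kind) for v in truth
        ]

    def test_round_trip_many_seeds(self):
        for seed in range(60):
            spec = AlleleSimSpec(
                length=300, n_snps=5, n_silent=2, indel_lengths=[3], seed=seed
            )
            ref, alt, truth = simulate_allele_pair(spec)
            called = call_variants(align_global(ref, alt))
            assert apply_variants(ref.residues, called) == alt.residues
            assert [(v.ref_pos, v.ref_allele, v.alt_allele) for v in called] == [
                (v.ref_pos, v.ref_allele, v.alt_allele) for v in truth
            ]

    def test_insertion_called(self):
        ref = rec("ACGTACGTACGTACG")
        alt = rec("ACGTACGTTTACGTACG")
        aln = align_global(ref, alt)
        variants = call_variants(aln)
        inserted = [v for v in variants if v.kind == "insertion"]
        assert len(inserted) == 1
        assert apply_variants(ref.residues, variants) == alt.residues


class TestTranslateCds:
    def test_standard_codons(self):
        assert translate_cds(rec("ATGGCC")).residues == "MA"

    def test_thr_and_pro_codons(self):
        assert translate_cds(rec("ACA")).residues == "T"
        assert translate_cds(rec("CCA")).residues == "P"

    def test_ambiguity_renders_x(self):
        assert translate_cds(rec("ATGNNN")).residues == "MX"

    def test_stop_rendered_as_star(self):
        assert translate_cds(rec("ATGTAA")).residues == "M*"

    def test_length_not_multiple_of_three_errors(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            translate_cds(rec("ACGT"))

    def test_protein_alphabet(self):
        assert translate_cds(rec("ATGGCC")).alphabet == "PROTEIN"


class TestClassifyEffects:
    def test_thr_to_pro_missense(self):
        # codon 2 ACC -> CCC: Thr -> Pro at aa 2
        ref = rec("ATGACCGGGTAA")
        alt = rec("ATGCCCGGGTAA")
        variants = classify_effects(
            call_variants(align_global(ref, alt)), ref, alt, cds_offset=0
        )
        (v,) = variants
        assert v.effect == "missense"
        assert v.aa_change == ("T", 2, "P")

    def test_third_position_silent(self):
        # GCT -> GCC, both Ala
        ref = rec("ATGGCTGGGTAA")
        alt = rec("ATGGCCGGGTAA")
        (v,) = classify_effects(
            call_variants(align_global(ref, alt)), ref, alt, cds_offset=0
        )
        assert v.effect == "silent"
        assert v.aa_change is None

    def test_in_frame_deletion_at_planted_codon(self):
        spec = AlleleSimSpec(length=2100, n_snps=0, n_silent=0, indel_lengths=[3], seed=3)
        ref, alt, truth = simulate_allele_pair(spec)
        called = compare_alleles(ref, alt)
        (v,) = [x for x in called if x.kind == "deletion"]
        assert v.effect == "in_frame_deletion"
        assert v.ref_pos == truth[0].ref_pos
        assert v.aa_change[2] == "-"
        # conceptual translations differ by exactly one residue; the reported
        # position must lie in the (possibly ambiguous) run of removable ones
        p_ref = translate_cds(ref).residues
        p_alt = translate_cds(alt).residues
        assert len(p_ref) == len(p_alt) + 1
        candidates = [
            j + 1
            for j in range(len(p_ref))
            if p_ref[:j] + p_ref[j + 1 :] == p_alt
        ]
        assert candidates
        assert min(candidates) <= v.aa_change[1] <= max(candidates)

    def test_in_frame_deletion_at_codon_654(self):
        # non-repetitive context: deletion stays codon-aligned at aa 654
        codons = ["ATG"] + ["GCA", "TGC", "GAT"] * 400 + ["TAA"]
        ref_seq = "".join(codons[:700]) + "ACC" + "".join(codons[700:])
        ref = rec(ref_seq)  # ACC (Thr) occupies codon 701
        assert translate_cds(ref).residues[700] == "T"
        variants = [Variant(700 * 3 + 1, "ACC", "", "deletion")]
        alt = rec(apply_variants(ref.residues, variants))
        (v,) = classify_effects(variants, ref, alt)
        assert v.effect == "in_frame_deletion"
        assert v.aa_change == ("T", 701, "-")

    def test_frameshift_deletion(self):
        ref = rec("ATGACCGGGACCTAA")
        variants = [Variant(5, "CC", "", "deletion")]
        alt = rec(apply_variants(ref.residues, variants))
        (v,) = classify_effects(variants, ref, alt)
        assert v.effect == "frameshift"

    def test_noncoding_with_offset(self):
        ref = rec("TTTTTATGACCTAA")  # CDS starts at base 6
        alt = rec("TTATTATGACCTAA")
        variants = call_variants(align_global(ref, alt))
        out = classify_effects(variants, ref, alt, cds_offset=5)
        assert [v.effect for v in out] == ["noncoding"]

    def test_offset_shifts_codon_frame(self):
        ref = rec("TTATGACCGGGTAA")  # 2-base leader, CDS from base 3
        alt = rec("TTATGCCCGGGTAA")
        (v,) = classify_effects(
            call_variants(align_global(ref, alt)), ref, alt, cds_offset=2
        )
        assert v.effect == "missense"
        assert v.aa_change == ("T", 2, "P")

    def test_inconsistent_allele_errors(self):
        ref = rec("ATGACCGGGTAA")
        alt = rec("ATGCCCGGGTAA")
        with pytest.raises(ValueError, match="mismatch"):
            classify_effects([Variant(4, "G", "C", "SNP")], ref, alt)

    def test_agrees_with_translate_and_diff_oracle(self):
        for seed in range(40):
            spec = AlleleSimSpec(length=420, n_snps=6, n_silent=3, seed=seed)
            ref, alt, truth = simulate_allele_pair(spec)
            out = compare_alleles(ref, alt)
            p_ref = translate_cds(ref).residues
            p_alt = translate_cds(alt).residues
            diff = {
                i + 1: (a, b) for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b
            }
            missense = {v.aa_change[1]: (v.aa_change[0], v.aa_change[2])
                        for v in out if v.effect == "missense"}
            assert missense == diff
            assert sum(1 for v in out if v.effect == "silent") == 3


class TestFindLongestOrf:
    def test_cds_with_utrs(self):
        cds = "ATG" + "GCAACC" * 50 + "TAA"
        record = rec("TTATTT" + cds + "ATTATT")
        offset, length = find_longest_orf(record)
        assert offset == 6
        assert length == len(cds)

    def test_picks_longest_of_two(self):
        short = "ATGTAA"
        long = "ATG" + "GGG" * 10 + "TGA"
        record = rec(short + "TT" + long)
        offset, length = find_longest_orf(record)
        assert record.residues[offset : offset + length] == long

    def test_no_orf_errors(self):
        with pytest.raises(ValueError, match="no complete ORF"):
            find_longest_orf(rec("ACCACCACC"))

    def test_simulated_cds_is_its_own_orf(self):
        spec = AlleleSimSpec(length=600, n_snps=0, n_silent=0, seed=1)
        ref, _, _ = simulate_allele_pair(spec)
        assert find_longest_orf(ref) == (0, 600)


class TestAssignDomains:
    def test_ssiii_aa_654_is_n_terminal(self):
        v = Variant(1960, "ACC", "", "deletion", effect="in_frame_deletion",
                    aa_change=("T", 654, "-"))
        (out,) = assign_domains([v], SSIII_DOMAINS)
        assert out.domain == "N-terminal"

    @pytest.mark.parametrize(
        "aa_pos,domain",
        [(1, "N-terminal"), (768, "N-terminal"), (769, "homology"),
         (1226, "homology"), (1227, "catalytic"), (1674, "catalytic")],
    )
    def test_boundaries(self, aa_pos, domain):
        v = Variant(aa_pos * 3, "A", "C", "SNP", effect="missense",
                    aa_change=("T", aa_pos, "P"))
        (out,) = assign_domains([v], SSIII_DOMAINS)
        assert out.domain == domain

    def test_outside_map_flagged(self):
        v = Variant(6000, "A", "C", "SNP", effect="missense",
                    aa_change=("T", 2000, "P"))
        (out,) = assign_domains([v], SSIII_DOMAINS)
        assert out.domain == "outside"

    def test_noncoding_uses_nt_intervals(self):
        v = Variant(2400, "A", "C", "SNP", effect="silent")
        (out,) = assign_domains([v], SSIII_DOMAINS)
        assert out.domain == "homology"

    def test_overlapping_map_errors(self):
        with pytest.raises(ValueError, match="overlap"):
            DomainMap(entries=[("a", 1, 30, 1, 10), ("b", 25, 60, 9, 20)])


class TestSummarizeAlleles:
    def test_empty(self):
        assert summarize_alleles([]) == {
            "n_snps": 0, "n_silent": 0, "n_missense": 0,
            "n_noncoding": 0, "n_indels": 0,
        }

    def test_synthetic_twelve_snps_five_silent(self):
        spec = AlleleSimSpec(length=900, n_snps=12, n_silent=5, seed=11)
        ref, alt, _ = simulate_allele_pair(spec)
        counts = summarize_alleles(compare_alleles(ref, alt))
        assert counts == {
            "n_snps": 12, "n_silent": 5, "n_missense": 7,
            "n_noncoding": 0, "n_indels": 0,
        }

    def test_partition_property(self):
        spec = AlleleSimSpec(length=600, n_snps=8, n_silent=4,
                             indel_lengths=[3, 6], seed=2)
        ref, alt, _ = simulate_allele_pair(spec)
        counts = summarize_alleles(compare_alleles(ref, alt))
        assert counts["n_silent"] + counts["n_missense"] + counts["n_noncoding"] \
            == counts["n_snps"]
        assert counts["n_indels"] == 2
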