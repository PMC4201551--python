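"""Consensus-to-reference alignment, variant typing, homopolymer context."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastidbarcoder import synth, variants as V
from plastidbarcoder.seq_io import Plastome
from plastidbarcoder.variants import (
    ConsensusAlignment,
    Variant,
    align_consensus,
    annotate_homopolymer,
    apply_variants,
    classify_substitution,
    extract_variants,
    gc_content,
    homopolymer_census,
    left_normalize,
    summarize_bias,
)


def affine_oracle(a, b, mm=1, go=2, ge=1):
    INF = 10 ** 9
    m, n = len(a), len(b)
    D = [[INF] * (n + 1) for _ in range(m + 1)]
    P = [[INF] * (n + 1) for _ in range(m + 1)]
    Q = [[INF] * (n + 1) for _ in range(m + 1)]
    D[0][0] = 0
    for j in range(1, n + 1):
        Q[0][j] = min(D[0][j - 1] + go + ge, Q[0][j - 1] + ge)
        D[0][j] = Q[0][j]
    for i in range(1, m + 1):
        P[i][0] = min(D[i - 1][0] + go + ge, P[i - 1][0] + ge)
        D[i][0] = P[i][0]
        for j in range(1, n + 1):
            P[i][j] = min(D[i - 1][j] + go + ge, P[i - 1][j] + ge)
            Q[i][j] = min(D[i][j - 1] + go + ge, Q[i][j - 1] + ge)
            s = 0 if a[i - 1] == b[j - 1] else mm
            D[i][j] = min(D[i - 1][j - 1] + s, P[i][j], Q[i][j])
    return D[m][n]


class TestAlignConsensus:
    def test_identical_sequences_no_differences(self, genome_5kb):
        aln = align_consensus(genome_5kb.sequence, genome_5kb)
        assert aln.cost == 0
        assert extract_variants(aln) == []

    def test_single_deleted_base_single_gap_column(self, genome_5kb):
        s = genome_5kb.sequence
        cons = s[:2000] + s[2001:]
        aln = align_consensus(cons, genome_5kb)
        dels = [(op, ln) for op, ln in aln.ops if op == "D"]
        assert dels == [("D", 1)]

    @pytest.mark.parametrize("seed", range(3))
    def test_anchored_equals_full_dp_on_2kb_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=2000))
        b = list(a)
        for _ in range(10):
            p = int(rng.integers(0, len(b)))
            u = rng.random()
            if u < 0.5:
                b[p] = str(rng.choice(list("ACGT")))
            elif u < 0.75:
                del b[p]
            else:
                b.insert(p, str(rng.choice(list("ACGT"))))
        b = "".join(b)
        from plastidbarcoder._align import anchored_global_align
        cost, _ops = anchored_global_align(b, a)
        assert cost == affine_oracle(b, a)

    def test_gross_length_disparity_rejected(self, genome_5kb):
        with pytest.raises(ValueError, match="disparity"):
            align_consensus(genome_5kb.sequence[:1000], genome_5kb)


class TestExtractVariants:
    def test_adjacent_substitutions_merge_into_mnv(self, genome_5kb):
        s = genome_5kb.sequence
        p = 1200
        alt = "".join({"A": "C", "C": "G", "G": "T", "T": "A"}[c]
                      for c in s[p:p + 2])
        cons = s[:p] + alt + s[p + 2:]
        out = extract_variants(align_consensus(cons, genome_5kb))
        assert len(out) == 1
        v = out[0]
        assert (v.type, v.position, v.ref_allele, v.alt_allele) == \
            ("MNV", p + 1, s[p:p + 2], alt)

    def test_snps_separated_by_a_match_stay_separate(self):
        ref = Plastome("r", "AAAACCCCGGGGTTTTAAAACCCCGGGG")
        cons = "AAAACCGCGCGGTTTTAAAACCCCGGGG"  # subs at 7 and 9, match at 8
        out = extract_variants(align_consensus(cons, ref))
        assert [v.type for v in out] == ["SNP", "SNP"]

    def test_deletion_reported_at_first_deleted_base(self):
        ref = Plastome("r", "ACGTACGTACGTACGTACGTACGT")
        cons = ref.sequence[:10] + ref.sequence[12:]
        out = extract_variants(align_consensus(cons, ref))
        assert len(out) == 1 and out[0].type == "del"
        assert len(out[0].ref_allele) == 2

    def test_roundtrip_extract_after_apply_recovers_truth(self):
        for seed in (1, 2, 3):
            g = synth.generate_plastome(
                synth.GenomeSpec(length=3_000, ir_length=0, seed=seed))
            mut, truth = synth.implant_variants(
                g, synth.VariantSpec(n_snp=6, n_mnv=1, n_ins=3, n_del=3,
                                     seed=seed))
            out = extract_variants(align_consensus(mut, g))
            assert [(v.position, v.type, v.ref_allele, v.alt_allele)
                    for v in out] == \
                   [(v.position, v.type, v.ref_allele, v.alt_allele)
                    for v in truth]


class TestClassifySubstitution:
    def test_exhaustive_ordered_pairs(self):
        transitions = [(a, b) for a in "ACGT" for b in "ACGT" if a != b
                       and classify_substitution(a, b) == "transition"]
        transversions = [(a, b) for a in "ACGT" for b in "ACGT" if a != b
                         and classify_substitution(a, b) == "transversion"]
        assert sorted(transitions) == [("A", "G"), ("C", "T"),
                                       ("G", "A"), ("T", "C")]
        assert len(transversions) == 8

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")


class TestHomopolymerContext:
    def test_insertion_inside_long_a_run(self):
        ref = Plastome("r", "CGT" + "A" * 10 + "CGTCG" * 4)
        v = annotate_homopolymer(Variant(3, "ins", "-", "A"), ref)
        assert (v.context.base, v.context.run_length) == ("A", 10)

    def test_isolated_deletion_run_length_one(self):
        ref = Plastome("r", "ACTGACTGACTG")
        v = annotate_homopolymer(Variant(4, "del", "G", "-"), ref)
        assert v.context.run_length == 1

    def test_toy_deletion_in_c_run(self):
        ref = Plastome("r", "AACCCGT")
        v = annotate_homopolymer(Variant(4, "del", "C", "-"), ref)
        assert (v.context.base, v.context.run_length) == ("C", 3)
        assert v.context.interval == (3, 5)

    def test_mixed_multibase_indel_flagged(self):
        ref = Plastome("r", "AACCCGTACGTACG")
        v = annotate_homopolymer(Variant(4, "del", "CCG", "-"), ref)
        assert v.context.mixed and v.context.base == "C"


class TestCensus:
    def test_single_run(self):
        assert homopolymer_census("AAAA") == {4: 1}

    def test_random_sequence_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=1000))

        def brute(seq, flt, min_len):
            import re
            out = {}
            for m in re.finditer(r"(A+|C+|G+|T+)", seq):
                ln = len(m.group())
                cls = "AT" if m.group()[0] in "AT" else "GC"
                if ln >= min_len and (flt is None or cls == flt):
                    out[ln] = out.get(ln, 0) + 1
            return out

        for flt in (None, "AT", "GC"):
            for mn in (1, 2, 3):
                assert homopolymer_census(seq, flt, mn) == brute(seq, flt, mn)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_census_mass_equals_sequence_length(self, seq):
        cen = homopolymer_census(seq)
        assert sum(L * n for L, n in cen.items()) == len(seq)


class TestBiasSummary:
    def test_empty(self):
        s = summarize_bias([])
        assert s.grand_total == 0

    def test_gc_at_split_totals(self):
        ref_seq = ("AAATTTAAATTTAAA" + "GGGCCCGGGCCCGGG") * 400
        ref = Plastome("r", ref_seq)
        fixture = []
        pos_gc = [i + 1 for i, c in enumerate(ref_seq) if c in "GC"]
        pos_at = [i + 1 for i, c in enumerate(ref_seq) if c in "AT"]
        for i in range(53):
            p = pos_gc[i * 7]
            fixture.append(annotate_homopolymer(
                Variant(p, "del", ref_seq[p - 1], "-"), ref))
        for i in range(44):
            p = pos_at[i * 7]
            fixture.append(annotate_homopolymer(
                Variant(p, "del", ref_seq[p - 1], "-"), ref))
        s = summarize_bias(fixture)
        assert s.totals_by_class == {"GC": 53, "AT": 44}
        assert s.grand_total == 97

    def test_duplicates_removed_before_counting(self):
        ref = Plastome("r", "AACCCGTAACCCGT")
        v = annotate_homopolymer(Variant(4, "del", "C", "-"), ref)
        s = summarize_bias([v, v])
        assert s.grand_total == 1

    def test_unannotated_variant_rejected(self):
        with pytest.raises(ValueError, match="annotation"):
            summarize_bias([Variant(4, "del", "C", "-")])


class TestScalars:
    def test_gc_content(self):
        assert gc_content("GGCC") == 1.0
        assert gc_content("AATT") == 0.0
        with pytest.raises(ValueError):
            gc_content("")

    def test_left_normalize_deletion_in_repeat(self):
        ref = "ACCCCGT"
        v = left_normalize(ref, Variant(5, "del", "C", "-"))
        assert v.position == 2

    def test_left_normalize_insertion_rotates_allele(self):
        ref = "ACCCCGT"
        v = left_normalize(ref, Variant(5, "ins", "-", "C"))
        assert v.position == 1 and v.alt_allele == "C"

    def test_variant_invariants_enforced(self):
        with pytest.raises(ValueError):
            Variant(1, "SNP", "AA", "CC")
        with pytest.raises(ValueError):
            Variant(1, "ins", "A", "C")
        with pytest.raises(ValueError):
            Variant(1, "del", "A", "C")
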