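"""Discrepancy detection, evidence rules, amendment, remap validation."""

import pytest

from plastidbarcoder import synth
from plastidbarcoder.reconcile import (
    ABSENT,
    DiscrepancyRecord,
    EvidenceBundle,
    ResolutionRules,
    amend_consensus,
    diff_variant_sets,
    gather_evidence,
    resolve,
    validate_by_remap,
)
from plastidbarcoder.seq_io import Plastome, ReadSet
from plastidbarcoder.variants import HomopolymerContext, Variant


def hp(base, run):
    return HomopolymerContext(base, "AT" if base in "AT" else "GC", run,
                              (1, run))


class TestDiff:
    def test_identical_sets_give_no_records(self):
        vs = [Variant(10, "SNP", "A", "T"), Variant(30, "del", "C", "-")]
        assert diff_variant_sets(vs, list(vs)) == []

    def test_one_sided_variant_reported(self):
        a = [Variant(10, "SNP", "A", "T")]
        b = [Variant(10, "SNP", "A", "T"), Variant(20, "del", "G", "-")]
        recs = diff_variant_sets(a, b)
        assert len(recs) == 1
        assert (recs[0].category, recs[0].position) == ("b_only", 20)

    def test_snp_vs_deletion_at_same_position_is_one_conflict(self):
        a = [Variant(17368, "SNP", "C", "A")]
        b = [Variant(17368, "del", "C", "-")]
        recs = diff_variant_sets(a, b)
        assert len(recs) == 1 and recs[0].category == "conflicting"

    def test_insertion_anchor_does_not_match_snp_position(self):
        a = [Variant(100, "ins", "-", "T")]
        b = [Variant(100, "SNP", "G", "T")]
        recs = diff_variant_sets(a, b)
        assert sorted(r.category for r in recs) == ["a_only", "b_only"]

    def test_different_references_rejected(self):
        with pytest.raises(ValueError, match="different references"):
            diff_variant_sets([], [], ref_id_a="x", ref_id_b="y")


class TestResolveRules:
    def _record(self, category="b_only", vtype="del", ref_allele="C",
                alt="-", position=100):
        rec = DiscrepancyRecord(position=position,
                                is_insertion=vtype == "ins",
                                ref_allele=ref_allele if vtype != "ins" else "-")
        v = Variant(position, vtype, rec.ref_allele, alt)
        if category == "a_only":
            rec.variant_a = v
        else:
            rec.variant_b = v
        rec.category = category
        return rec

    def test_r1_mapping_artifact_keeps_reference(self):
        rec = self._record(category="b_only", vtype="MNV", ref_allele="TT",
                           alt="AA")
        ev = EvidenceBundle(contig_alleles={"a": "TT", "b": "TT"},
                            homopolymer=hp("T", 1), mapping_ambiguity=True)
        out = resolve(rec, ev)
        assert (out.rule, out.resolved_allele) == ("R1", "TT")

    def test_r2_contig_supported_variant_adopted(self):
        rec = self._record(category="b_only", vtype="ins", alt="TCCTATTTAATA")
        ev = EvidenceBundle(
            contig_alleles={"a": "TTCCTATTTAATA", "b": "TTCCTATTTAATA"},
            homopolymer=hp("T", 1))
        out = resolve(rec, ev)
        assert (out.rule, out.resolution) == ("R2", "adopt_contig")
        assert out.resolved_allele == "TTCCTATTTAATA"

    def test_r3_homopolymer_read_error_keeps_reference(self):
        rec = self._record(category="b_only", vtype="del", ref_allele="C")
        ev = EvidenceBundle(contig_alleles={"a": "C", "b": "C"},
                            homopolymer=hp("C", 3), mapping_ambiguity=False)
        out = resolve(rec, ev)
        assert (out.rule, out.resolved_allele) == ("R3", "C")

    def test_r4_long_homopolymer_disagreement_unresolved(self):
        rec = DiscrepancyRecord(position=3545, is_insertion=True,
                                ref_allele="-",
                                variant_a=Variant(3545, "ins", "-", "AA"),
                                variant_b=Variant(3545, "ins", "-", "A"),
                                category="conflicting")
        ev = EvidenceBundle(contig_alleles={"a": "AA", "b": "AAA"},
                            homopolymer=hp("A", 10))
        out = resolve(rec, ev)
        assert (out.rule, out.resolution) == ("R4", "unresolved")
        assert out.resolved_allele == "-" and out.uncertain

    def test_conflicting_snps_with_contig_support_adopt_contig_allele(self):
        # contigs agreeing on one platform's non-reference allele are
        # already conclusive contig evidence (R2 subsumes the default rule)
        rec = DiscrepancyRecord(position=50, is_insertion=False,
                                ref_allele="G",
                                variant_a=Variant(50, "SNP", "G", "A"),
                                variant_b=Variant(50, "SNP", "G", "T"),
                                category="conflicting")
        ev = EvidenceBundle(contig_alleles={"x": "T", "y": "T"},
                            homopolymer=hp("G", 1))
        out = resolve(rec, ev)
        assert (out.rule, out.resolution, out.resolved_allele) == \
            ("R2", "adopt_contig", "T")

    def test_r5_single_platform_snp_with_reference_contigs(self):
        # an Illumina-only SNP, contigs quietly carrying the reference and
        # no mapping ambiguity: the contigs side with the other platform
        rec = self._record(category="a_only", vtype="SNP", ref_allele="G",
                           alt="A")
        ev = EvidenceBundle(contig_alleles={"x": "G", "y": "G"},
                            homopolymer=hp("G", 1), mapping_ambiguity=False)
        out = resolve(rec, ev)
        assert (out.rule, out.resolution, out.resolved_allele) == \
            ("R5", "adopt_b", "G")

    def test_no_contig_coverage_forces_unresolved_default_reference(self):
        rec = self._record()
        ev = EvidenceBundle(contig_alleles={"a": ABSENT, "b": ABSENT},
                            homopolymer=hp("C", 2))
        out = resolve(rec, ev)
        assert out.resolution == "unresolved" and out.resolved_allele == "C"
        assert out.uncertain

    def test_long_homopolymer_threshold_configurable(self):
        rec = self._record(vtype="ins", alt="A", position=200)
        ev = EvidenceBundle(contig_alleles={"a": "A", "b": "AA"},
                            homopolymer=hp("A", 6))
        out = resolve(rec, ev, ResolutionRules(long_homopolymer=6))
        assert out.rule == "R4"


class TestAmend:
    def test_no_edits_is_identity(self, genome_5kb):
        amended, applied = amend_consensus(genome_5kb, [], [])
        assert amended == genome_5kb.sequence and applied == []

    def test_insertion_and_deletion_length_arithmetic(self):
        ref = Plastome("toy", "ACGT" * 250)
        rec_ins = DiscrepancyRecord(position=100, is_insertion=True,
                                    ref_allele="-", resolution="adopt_contig",
                                    resolved_allele="TTCCTATTTAATA")
        rec_del = DiscrepancyRecord(position=500, is_insertion=False,
                                    ref_allele=ref.sequence[499],
                                    resolution="adopt_b", resolved_allele="-")
        amended, applied = amend_consensus(ref, [rec_ins, rec_del], [])
        assert len(amended) == 1000 + 13 - 1
        assert len(applied) == 2

    def test_reference_and_unresolved_records_apply_nothing(self, genome_5kb):
        recs = [DiscrepancyRecord(position=10, is_insertion=False,
                                  ref_allele="A", resolution="reference",
                                  resolved_allele="A"),
                DiscrepancyRecord(position=20, is_insertion=False,
                                  ref_allele="C", resolution="unresolved",
                                  resolved_allele="C", uncertain=True)]
        amended, applied = amend_consensus(genome_5kb, recs, [])
        assert amended == genome_5kb.sequence and applied == []

    def test_overlapping_edits_rejected(self):
        ref = Plastome("toy", "ACGT" * 50)
        r1 = DiscrepancyRecord(position=10, is_insertion=False,
                               ref_allele=ref.sequence[9:12],
                               resolution="adopt_a", resolved_allele="TTT")
        r2 = DiscrepancyRecord(position=11, is_insertion=False,
                               ref_allele=ref.sequence[10],
                               resolution="adopt_b", resolved_allele="-")
        with pytest.raises(ValueError, match="overlapping"):
            amend_consensus(ref, [r1, r2], [])

    def test_amend_roundtrip_reextraction(self, genome_5kb):
        from plastidbarcoder.variants import align_consensus, extract_variants
        shared = [Variant(400, "SNP", genome_5kb.sequence[399],
                          "A" if genome_5kb.sequence[399] != "A" else "G")]
        rec = DiscrepancyRecord(position=900, is_insertion=False,
                                ref_allele=genome_5kb.sequence[899],
                                resolution="adopt_b", resolved_allele="-")
        amended, _ = amend_consensus(genome_5kb, [rec], shared)
        out = extract_variants(align_consensus(amended, genome_5kb))
        assert len(out) == 2
        assert {v.type for v in out} == {"SNP", "del"}


class TestEvidenceAndRemap:
    def test_contig_allele_read_from_scaffold(self, genome_5kb):
        from plastidbarcoder.assembly import Contig, ScaffoldAlignment
        s = genome_5kb.sequence
        # pick a deletion site that is already left-normalized
        p = next(p for p in range(1000, 1100)
                 if s[p - 2] != s[p - 1] and s[p - 1] != s[p])
        contig_del = Contig("c1", s[500:p - 1] + s[p:1500])
        contig_ref = Contig("c2", s[500:1500])
        sc_del = ScaffoldAlignment("c1", 501, 1500, "+", 1.0, 0.999, 999)
        sc_ref = ScaffoldAlignment("c2", 501, 1500, "+", 1.0, 1.0, 1000)
        rec = DiscrepancyRecord(position=p, is_insertion=False,
                                ref_allele=s[p - 1],
                                variant_b=Variant(p, "del", s[p - 1], "-"),
                                category="b_only")
        ev = gather_evidence(rec, {"del_src": ([contig_del], [sc_del]),
                                   "ref_src": ([contig_ref], [sc_ref])},
                             genome_5kb)
        assert ev.contig_alleles["del_src"] == "-"
        assert ev.contig_alleles["ref_src"] == s[p - 1]

    def test_uncovered_site_recorded_absent(self, genome_5kb):
        from plastidbarcoder.assembly import Contig, ScaffoldAlignment
        contig = Contig("c1", genome_5kb.sequence[2000:2500])
        sc = ScaffoldAlignment("c1", 2001, 2500, "+", 1.0, 1.0, 500)
        rec = DiscrepancyRecord(position=100, is_insertion=False,
                                ref_allele=genome_5kb.sequence[99],
                                category="b_only")
        ev = gather_evidence(rec, {"src": ([contig], [sc])}, genome_5kb)
        assert ev.contig_alleles["src"] == ABSENT

    def test_remap_with_no_reads_returns_empty(self, genome_5kb):
        assert validate_by_remap(genome_5kb.sequence, ReadSet([])) == []

    def test_remap_confirms_clean_amendment(self):
        g = synth.generate_plastome(synth.GenomeSpec(length=3_000, ir_length=0,
                                                     seed=71))
        mut, _ = synth.implant_variants(
            g, synth.VariantSpec(n_snp=4, n_mnv=0, n_ins=1, n_del=1, seed=72))
        reads = synth.simulate_reads(
            mut, synth.ErrorModel.illumina(substitution_rate=0.0, paired=False),
            30, seed=73)
        assert validate_by_remap(mut, reads) == []
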