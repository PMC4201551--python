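"""Cross-platform variant reconciliation.

Two platforms' mapping-consensus variant sets are diffed into discrepancy
records (variant in one consensus absent or different in the other). Each
record is resolved by evidence rules that codify the manual validation
procedure — inspect the mapping for ambiguity, and read the allele out of
de novo contigs from independent assemblies:

R1  mapping artifact: contigs from every source carry the reference
    allele and the site shows mapping ambiguity -> keep the reference.
R2  contig-supported variant: all contig sources agree on one
    non-reference allele -> adopt it (catches long insertions missed by
    mapping).
R3  homopolymer read error: a single-platform indel in a run of >= 2
    bases whose contigs carry the reference allele -> keep the reference.
R4  long-homopolymer ambiguity: an indel in a run of >= 8 bases where the
    contig sources disagree among themselves -> unresolved (reference
    kept, flagged uncertain).
R5  default: contigs agree with exactly one platform -> adopt that
    platform's allele; otherwise unresolved.

Mapping ambiguity replaces visual inspection (and the read-level nuclear
paralog check) with a statistic: within +-25 bp of the site, more than 20%
of covering reads carry >= 3 differences or were randomly-placed
multimappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from plastidbarcoder import refmap as _refmap
from plastidbarcoder.seq_io import Plastome, ReadSet, revcomp
from plastidbarcoder.variants import (
    ConsensusAlignment,
    HomopolymerContext,
    Variant,
    _run_at,
    align_consensus,
    annotate_homopolymer,
    extract_variants,
    left_normalize,
)
from plastidbarcoder import _align

logger = logging.getLogger(__name__)

ABSENT = "absent"


@dataclass
class EvidenceBundle:
    contig_alleles: dict[str, str] = field(default_factory=dict)
    homopolymer: Optional[HomopolymerContext] = None
    mapping_ambiguity: bool = False
    platform_of_variant: Optional[str] = None

    @property
    def present_alleles(self) -> list[str]:
        return [a for a in self.contig_alleles.values() if a != ABSENT]


@dataclass
class DiscrepancyRecord:
    position: int
    is_insertion: bool
    ref_allele: str
    variant_a: Optional[Variant] = None
    variant_b: Optional[Variant] = None
    category: str = ""                  # a_only | b_only | conflicting
    evidence: Optional[EvidenceBundle] = None
    resolution: Optional[str] = None    # reference|adopt_a|adopt_b|adopt_contig|unresolved
    resolved_allele: Optional[str] = None
    rule: Optional[str] = None
    uncertain: bool = False

    @property
    def locus(self) -> tuple[int, bool]:
        return (self.position, self.is_insertion)

    @property
    def anchor_label(self) -> str:
        if self.is_insertion:
            return f"{self.position}^{self.position + 1}"
        return str(self.position)

    def allele_of(self, side: str) -> str:
        """The allele a platform's consensus carries at this locus."""
        v = self.variant_a if side == "a" else self.variant_b
        if v is None:
            return "-" if self.is_insertion else self.ref_allele
        return v.alt_allele


# ---------------------------------------------------------------------------
# Diff
# ---------------------------------------------------------------------------

def diff_variant_sets(set_a: Sequence[Variant], set_b: Sequence[Variant],
                      ref_id_a: Optional[str] = None,
                      ref_id_b: Optional[str] = None) -> list[DiscrepancyRecord]:
    """Discrepancies between two left-normalized variant sets.

    Variants are matched by locus — insertions by anchor, everything else
    by start position (a SNP on one platform and a deletion on the other
    at the same position are one conflicting record). Shared identical
    variants are excluded.
    """
    if ref_id_a is not None and ref_id_b is not None and ref_id_a != ref_id_b:
        raise ValueError(f"variant sets from different references: "
                         f"{ref_id_a!r} vs {ref_id_b!r}")
    a_by_locus = {v.locus: v for v in set_a}
    b_by_locus = {v.locus: v for v in set_b}
    records: list[DiscrepancyRecord] = []
    for locus in sorted(set(a_by_locus) | set(b_by_locus)):
        va = a_by_locus.get(locus)
        vb = b_by_locus.get(locus)
        if va is not None and vb is not None:
            if va.type == vb.type and va.alt_allele == vb.alt_allele \
                    and va.ref_allele == vb.ref_allele:
                continue  # shared call
            category = "conflicting"
        elif va is not None:
            category = "a_only"
        else:
            category = "b_only"
        ref_allele = (va or vb).ref_allele
        records.append(DiscrepancyRecord(
            position=locus[0], is_insertion=locus[1], ref_allele=ref_allele,
            variant_a=va, variant_b=vb, category=category,
        ))
    return records


# ---------------------------------------------------------------------------
# Evidence
# ---------------------------------------------------------------------------

def _contig_allele_at(record: DiscrepancyRecord, contigs, scaffolds,
                      ref: Plastome, margin: int = 40) -> str:
    """Read the allele a contig set carries at the record's locus."""
    by_id = {c.id: c for c in contigs}
    pos = record.position
    span = 1 if record.ref_allele == "-" else len(record.ref_allele)
    ws = max(0, pos - 1 - margin)
    we = min(len(ref.sequence), pos - 1 + span + margin)
    window = ref.sequence[ws:we]
    for sc in scaffolds:
        if sc.ref_start > ws + 1 or sc.ref_end < we:
            continue
        contig = by_id[sc.contig_id].sequence
        if sc.strand == "-":
            contig = revcomp(contig)
        hit = edlib.align(window, contig, mode="HW", task="locations")
        if hit["editDistance"] < 0:
            continue
        s, e = hit["locations"][0]
        seg = contig[s : e + 1]
        cost, ops = _align.affine_global_align(seg, window)
        aln = ConsensusAlignment(query=seg, ref=window, ops=ops, cost=cost,
                                 ref_offset=ws)
        calls = [left_normalize(ref.sequence, v) if v.type in ("ins", "del") else v
                 for v in extract_variants(aln, normalize=False)]
        found = [v for v in calls if v.locus == record.locus]
        if found:
            return found[0].alt_allele
        return "-" if record.is_insertion else record.ref_allele
    return ABSENT


def gather_evidence(record: DiscrepancyRecord,
                    contigs_by_source: dict[str, tuple],
                    ref: Plastome,
                    alignments_by_platform: Optional[dict[str, list]] = None,
                    window: int = 25, diff_floor: int = 3,
                    ambiguous_fraction: float = 0.2) -> EvidenceBundle:
    """Collect the evidence a record is resolved on.

    ``contigs_by_source`` maps an assembly source name to a
    ``(contigs, scaffold_alignments)`` pair; a source with no contig
    covering the site is recorded as absent. ``alignments_by_platform``
    (read-to-reference alignments) feeds the mapping-ambiguity statistic.
    """
    bundle = EvidenceBundle()
    for source, (contigs, scaffolds) in contigs_by_source.items():
        bundle.contig_alleles[source] = _contig_allele_at(
            record, contigs, scaffolds, ref)
    site_variant = next((v for v in (record.variant_b, record.variant_a)
                         if v is not None and v.type in ("ins", "del")),
                        record.variant_b or record.variant_a)
    if site_variant is not None:
        bundle.homopolymer = annotate_homopolymer(site_variant, ref).context
    else:
        lo, hi = _run_at(ref.sequence, record.position - 1)
        base = ref.sequence[record.position - 1]
        bundle.homopolymer = HomopolymerContext(
            base, "AT" if base in "AT" else "GC", hi - lo + 1,
            (lo + 1, hi + 1))
    if record.category == "a_only":
        bundle.platform_of_variant = "a"
    elif record.category == "b_only":
        bundle.platform_of_variant = "b"
    if alignments_by_platform:
        lo, hi = record.position - window, record.position + window
        for alns in alignments_by_platform.values():
            covering = [a for a in alns
                        if a.ref_start <= hi and a.ref_end >= lo]
            if not covering:
                continue
            flagged = sum(1 for a in covering
                          if a.n_diff >= diff_floor or a.multimapped)
            if flagged > ambiguous_fraction * len(covering):
                bundle.mapping_ambiguity = True
    return bundle


# ---------------------------------------------------------------------------
# Resolution rules
# ---------------------------------------------------------------------------

@dataclass
class ResolutionRules:
    long_homopolymer: int = 8


def resolve(record: DiscrepancyRecord, evidence: EvidenceBundle,
            rules: Optional[ResolutionRules] = None) -> DiscrepancyRecord:
    """Apply rules R1-R5 in order; every record receives a resolution."""
    rules = rules or ResolutionRules()
    record.evidence = evidence
    ref_allele = "-" if record.is_insertion else record.ref_allele
    present = evidence.present_alleles
    run_len = evidence.homopolymer.run_length if evidence.homopolymer else 1
    has_indel = any(v is not None and v.type in ("ins", "del")
                    for v in (record.variant_a, record.variant_b))
    single_platform = record.category in ("a_only", "b_only")

    def settle(resolution, allele, rule, uncertain=False):
        record.resolution = resolution
        record.resolved_allele = allele
        record.rule = rule
        record.uncertain = uncertain
        return record

    if not present:
        return settle("unresolved", ref_allele, "no_contig_evidence", True)
    agree = len(set(present)) == 1
    contig_allele = present[0] if agree else None

    # R1: mapping artifact
    if agree and contig_allele == ref_allele and evidence.mapping_ambiguity:
        return settle("reference", ref_allele, "R1")
    # R2: contig-supported variant
    if agree and contig_allele != ref_allele:
        return settle("adopt_contig", contig_allele, "R2")
    # R3: homopolymer read error
    if (single_platform and has_indel and run_len >= 2 and agree
            and contig_allele == ref_allele):
        return settle("reference", ref_allele, "R3")
    # R4: long-homopolymer ambiguity
    if has_indel and run_len >= rules.long_homopolymer and not agree:
        return settle("unresolved", ref_allele, "R4", True)
    # R5: default
    if agree:
        a_allele = record.allele_of("a")
        b_allele = record.allele_of("b")
        if (contig_allele == a_allele) != (contig_allele == b_allele):
            side = "a" if contig_allele == a_allele else "b"
            return settle(f"adopt_{side}", contig_allele, "R5")
    return settle("unresolved", ref_allele, "R5", True)


# ---------------------------------------------------------------------------
# Amendment and validation
# ---------------------------------------------------------------------------

def amend_consensus(ref: Plastome, resolved: Sequence[DiscrepancyRecord],
                    shared: Sequence[Variant] = ()) -> tuple[str, list]:
    """Apply shared variants plus non-reference resolutions to the
    reference, right-to-left. Overlapping edits raise an error naming the
    collision; identical duplicate edits collapse."""
    edits: list[tuple[int, int, str, str]] = []  # (start0, end0, replacement, label)
    for v in shared:
        if v.type == "ins":
            edits.append((v.position, v.position, v.alt_allele, v.anchor_label))
        elif v.type == "del":
            edits.append((v.position - 1, v.position - 1 + len(v.ref_allele),
                          "", str(v.position)))
        else:
            edits.append((v.position - 1, v.position - 1 + len(v.ref_allele),
                          v.alt_allele, str(v.position)))
    for r in resolved:
        if r.resolution in ("reference", "unresolved", None):
            continue
        allele = r.resolved_allele
        ref_allele = "" if r.ref_allele == "-" else r.ref_allele
        repl = "" if allele == "-" else allele
        if r.is_insertion:
            edits.append((r.position, r.position, repl, r.anchor_label))
        else:
            edits.append((r.position - 1, r.position - 1 + len(ref_allele),
                          repl, str(r.position)))
    edits = sorted(set(edits))
    for (s1, e1, _r1, l1), (s2, e2, _r2, l2) in zip(edits, edits[1:]):
        if s2 < e1 or (s2 == s1 and e2 == e1):
            raise ValueError(f"overlapping edits at {l1} and {l2}")
    out = ref.sequence
    applied = []
    for s, e, repl, label in reversed(edits):
        if out[s:e] == "" and repl == "":
            continue
        out = out[:s] + repl + out[e:]
        applied.append((label, ref.sequence[s:e] or "-", repl or "-"))
    return out, applied[::-1]


def validate_by_remap(amended: str, reads: ReadSet,
                      params: Optional[_refmap.MappingParams] = None
                      ) -> list[Variant]:
    """Re-map reads to the amended sequence and list every site where the
    fresh majority consensus still disagrees with it."""
    if len(reads) == 0:
        logger.warning("no reads supplied; remap validation skipped")
        return []
    params = params or _refmap.MappingParams()
    target = Plastome("amended", amended)
    alignments, _rep = _refmap.map_reads(reads, target, params)
    pile = _refmap.build_pileup(alignments, target)
    res = _refmap.call_consensus(pile, target)
    if res.consensus == amended:
        return []
    aln = align_consensus(res.consensus, amended)
    return extract_variants(aln)
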