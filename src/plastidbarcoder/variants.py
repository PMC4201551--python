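"""Variant extraction and classification against a reference plastome.

A consensus is aligned globally to the reference (unit mismatch, affine
gaps, anchor decomposition for chromosome-scale inputs); maximal runs of
substituted columns become SNPs (length 1) or MNVs (length >= 2), maximal
gap runs become insertions/deletions. Indels are left-normalized — shifted
to the leftmost equivalent position within a repeat — so that calls from
different platforms and assemblies land on comparable coordinates.
Homopolymer context (base class A/T vs G/C and maximal run length) drives
the platform bias profile.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from plastidbarcoder import _align
from plastidbarcoder.seq_io import Plastome

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class HomopolymerContext:
    base: str
    base_class: str          # "AT" | "GC"
    run_length: int
    interval: tuple[int, int]  # 1-based inclusive reference interval
    mixed: bool = False      # multi-base indel with mixed bases


@dataclass
class Variant:
    """A typed difference against the reference.

    ``position`` is 1-based; insertions are anchored between ``position``
    and ``position + 1`` (``ref_allele == "-"``), deletions start at the
    first deleted base (``alt_allele == "-"``).
    """

    position: int
    type: str                # "SNP" | "MNV" | "ins" | "del"
    ref_allele: str
    alt_allele: str
    substitution_class: Optional[str] = None
    context: Optional[HomopolymerContext] = None

    def __post_init__(self) -> None:
        if self.type == "SNP" and (len(self.ref_allele) != 1 or len(self.alt_allele) != 1):
            raise ValueError("SNP alleles must both be single bases")
        if self.type == "MNV" and (
            len(self.ref_allele) != len(self.alt_allele) or len(self.ref_allele) < 2
        ):
            raise ValueError("MNV alleles must be equal length >= 2")
        if self.type == "ins" and self.ref_allele != "-":
            raise ValueError("insertion must have ref_allele '-'")
        if self.type == "del" and self.alt_allele != "-":
            raise ValueError("deletion must have alt_allele '-'")
        if self.type == "SNP" and self.substitution_class is None:
            self.substitution_class = classify_substitution(self.ref_allele, self.alt_allele)

    @property
    def locus(self) -> tuple[int, bool]:
        """Matching key: (position, is_insertion). Insertions only match
        insertions at the same anchor; other types match by start position."""
        return (self.position, self.type == "ins")

    @property
    def anchor_label(self) -> str:
        if self.type == "ins":
            return f"{self.position}^{self.position + 1}"
        return str(self.position)


@dataclass
class ConsensusAlignment:
    """Global alignment of a query consensus against a reference."""

    query: str
    ref: str
    ops: list[tuple[str, int]]   # run-length over =, X, I, D
    cost: int
    ref_offset: int = 0          # 0-based offset of `ref` within the full reference


@dataclass
class BiasSummary:
    """Indel counts stratified by (type, homopolymer run length, base class)."""

    counts: dict[tuple[str, int, str], int] = field(default_factory=dict)

    @property
    def totals_by_class(self) -> dict[str, int]:
        out: dict[str, int] = {"AT": 0, "GC": 0}
        for (_t, _rl, cls), n in self.counts.items():
            out[cls] += n
        return out

    @property
    def grand_total(self) -> int:
        return sum(self.counts.values())

    def count(self, indel_type: str, base_class: str,
              run_lengths: Iterable[int]) -> int:
        rls = set(run_lengths)
        return sum(n for (t, rl, cls), n in self.counts.items()
                   if t == indel_type and cls == base_class and rl in rls)


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Transition (A<->G, C<->T) or transversion."""
    if ref_base == alt_base:
        raise ValueError("bases are identical; not a substitution")
    return "transition" if (ref_base, alt_base) in TRANSITIONS else "transversion"


def gc_content(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def base_class(base: str) -> str:
    return "AT" if base in "AT" else "GC"


# ---------------------------------------------------------------------------
# Applying / normalizing variants
# ---------------------------------------------------------------------------

def apply_variants(seq: str, variants: Sequence) -> str:
    """Apply variants (Variant or VariantTableRow-likes with a single alt)
    to ``seq``, right-to-left so coordinates stay valid."""
    out = seq
    for v in sorted(variants, key=lambda v: (-v.position, v.type != "ins")):
        alt = getattr(v, "alt_allele", None)
        if alt is None:  # VariantTableRow single-alt layout
            alt = v.allele_a
        p = v.position
        if v.type == "ins":
            out = out[:p] + alt + out[p:]
        elif v.type == "del":
            ref = v.ref_allele
            if out[p - 1 : p - 1 + len(ref)] != ref:
                raise ValueError(
                    f"deletion at {p}: reference disagreement "
                    f"({out[p-1:p-1+len(ref)]!r} != {ref!r})"
                )
            out = out[: p - 1] + out[p - 1 + len(ref):]
        else:  # SNP / MNV
            ref = v.ref_allele
            if out[p - 1 : p - 1 + len(ref)] != ref:
                raise ValueError(f"substitution at {p}: reference disagreement")
            out = out[: p - 1] + alt + out[p - 1 + len(ref):]
    return out


def left_normalize(ref: str, variant: Variant) -> Variant:
    """Shift an indel to its leftmost equivalent placement (repeat-aware)."""
    if variant.type == "del":
        pos, allele = variant.position, variant.ref_allele
        while pos > 1 and ref[pos - 2] == allele[-1]:
            allele = ref[pos - 2] + allele[:-1]
            pos -= 1
        return Variant(pos, "del", allele, "-", context=variant.context)
    if variant.type == "ins":
        pos, allele = variant.position, variant.alt_allele
        while pos > 0 and ref[pos - 1] == allele[-1]:
            allele = allele[-1] + allele[:-1]
            pos -= 1
        return Variant(pos, "ins", "-", allele, context=variant.context)
    return variant


# ---------------------------------------------------------------------------
# Alignment and extraction
# ---------------------------------------------------------------------------

def align_consensus(consensus: str, ref, mismatch: int = 1,
                    gap_open: int = 2, gap_extend: int = 1) -> ConsensusAlignment:
    """Globally align a consensus sequence to the reference.

    Guards against grossly mismatched inputs (length disparity over 20%).
    """
    refseq = ref.sequence if isinstance(ref, Plastome) else ref
    if not consensus or not refseq:
        raise ValueError("empty sequence")
    if abs(len(consensus) - len(refseq)) > 0.2 * max(len(consensus), len(refseq)):
        raise ValueError(
            f"length disparity beyond 20% ({len(consensus)} vs {len(refseq)}): "
            "wrong input?"
        )
    cost, ops = _align.anchored_global_align(
        consensus, refseq, mismatch=mismatch, gap_open=gap_open,
        gap_extend=gap_extend,
    )
    return ConsensusAlignment(query=consensus, ref=refseq, ops=ops, cost=cost)


def extract_variants(alignment: ConsensusAlignment,
                     normalize: bool = True) -> list[Variant]:
    """Turn an alignment into typed variants.

    Maximal runs of adjacent substituted columns merge into one MNV (or a
    SNP when length 1); maximal gap runs become one insertion or deletion.
    Indels are left-normalized against the full reference coordinate frame.
    """
    ref = alignment.ref
    query = alignment.query
    off = alignment.ref_offset
    out: list[Variant] = []
    qpos = rpos = 0
    i = 0
    ops = alignment.ops
    while i < len(ops):
        op, ln = ops[i]
        if op == "=":
            qpos += ln
            rpos += ln
            i += 1
        elif op == "X":
            # merge directly adjacent X runs (ops are already run-length
            # merged, so a single X run is one event)
            refa = ref[rpos : rpos + ln]
            alta = query[qpos : qpos + ln]
            vtype = "SNP" if ln == 1 else "MNV"
            out.append(Variant(off + rpos + 1, vtype, refa, alta))
            qpos += ln
            rpos += ln
            i += 1
        elif op == "D":
            refa = ref[rpos : rpos + ln]
            v = Variant(off + rpos + 1, "del", refa, "-")
            out.append(v)
            rpos += ln
            i += 1
        else:  # I
            alta = query[qpos : qpos + ln]
            v = Variant(off + rpos, "ins", "-", alta)
            out.append(v)
            qpos += ln
            i += 1
    if normalize:
        full_ref = ref  # extraction coordinates are already full-frame via off
        out = [left_normalize(full_ref, v) if v.type in ("ins", "del") else v
               for v in out]
    out.sort(key=lambda v: (v.position, v.type == "ins"))
    return out


# ---------------------------------------------------------------------------
# Homopolymer context
# ---------------------------------------------------------------------------

def _run_at(ref: str, pos0: int) -> tuple[int, int]:
    """Maximal run (0-based inclusive interval) containing position pos0."""
    base = ref[pos0]
    lo = pos0
    while lo > 0 and ref[lo - 1] == base:
        lo -= 1
    hi = pos0
    while hi + 1 < len(ref) and ref[hi + 1] == base:
        hi += 1
    return lo, hi


def annotate_homopolymer(variant: Variant, ref) -> Variant:
    """Attach the maximal homopolymer run at/adjacent to the variant site."""
    refseq = ref.sequence if isinstance(ref, Plastome) else ref
    mixed = False
    if variant.type == "del":
        allele = variant.ref_allele
        base = allele[0]
        mixed = len(set(allele)) > 1
        lo, hi = _run_at(refseq, variant.position - 1)
    elif variant.type == "ins":
        allele = variant.alt_allele
        base = allele[0]
        mixed = len(set(allele)) > 1
        a = variant.position  # anchor: between a and a+1 (1-based)
        if a >= 1 and refseq[a - 1] == base:
            lo, hi = _run_at(refseq, a - 1)
        elif a < len(refseq) and refseq[a] == base:
            lo, hi = _run_at(refseq, a)
        else:
            lo = hi = max(a - 1, 0)
            ctx = HomopolymerContext(base, base_class(base), 1,
                                     (lo + 1, hi + 1), mixed)
            variant.context = ctx
            return variant
    else:
        base = refseq[variant.position - 1]
        lo, hi = _run_at(refseq, variant.position - 1)
    variant.context = HomopolymerContext(
        base=base, base_class=base_class(base), run_length=hi - lo + 1,
        interval=(lo + 1, hi + 1), mixed=mixed,
    )
    return variant


def homopolymer_census(seq: str, base_filter: Optional[str] = None,
                       min_length: int = 1) -> dict[int, int]:
    """Count maximal homopolymer runs by length.

    ``base_filter`` restricts to the "AT" or "GC" base class (runs of C and
    runs of G are both counted under "GC").
    """
    census: Counter[int] = Counter()
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        ln = j - i + 1
        if ln >= min_length and (base_filter is None
                                 or base_class(seq[i]) == base_filter):
            census[ln] += 1
        i = j + 1
    return dict(census)


def summarize_bias(variants: Sequence[Variant]) -> BiasSummary:
    """Tally annotated indels by (type, run length, base class).

    Indels are deduplicated by (position, type, allele) first — merging
    calls of the same event from different analysis routes.
    """
    seen: set[tuple[int, str, str]] = set()
    summary = BiasSummary()
    for v in variants:
        if v.type not in ("ins", "del"):
            continue
        if v.context is None:
            raise ValueError(f"variant at {v.position} lacks homopolymer annotation")
        allele = v.alt_allele if v.type == "ins" else v.ref_allele
        key = (v.position, v.type, allele)
        if key in seen:
            continue
        seen.add(key)
        ck = (v.type, v.context.run_length, v.context.base_class)
        summary.counts[ck] = summary.counts.get(ck, 0) + 1
    return summary
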