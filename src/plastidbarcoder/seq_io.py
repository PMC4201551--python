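"""Sequence I/O and the domain types shared across the pipeline.

Coordinates are 1-based inclusive everywhere user-facing; insertions are
anchored between two reference positions and printed ``pos^pos+1``.
Quality scores are Sanger PHRED (+33 in FASTQ); the per-base error
probability ``p = 10**(-Q/10)`` defined here is the single quality-to-
probability conversion used pipeline-wide.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGT")
VALID_READ_BASES = set("ACGTN")
VARIANT_TYPES = ("SNP", "MNV", "ins", "del")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def phred_to_prob(q: int) -> float:
    """Per-base error probability for a PHRED score."""
    return 10.0 ** (-q / 10.0)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class AmbiguousBaseError(FormatError):
    """Raised when a genome sequence contains a non-A/C/G/T character."""


@dataclass
class Plastome:
    """A (reference or truth) plastome: linear A/C/G/T sequence with an
    optional pair of inverted-repeat intervals (1-based inclusive)."""

    id: str
    sequence: str
    ir_regions: Optional[tuple[tuple[int, int], tuple[int, int]]] = None
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(self.sequence, 1) if c in bad)
            raise AmbiguousBaseError(
                f"plastome {self.id!r}: non-ACGT character "
                f"{self.sequence[pos - 1]!r} at position {pos}"
            )
        if self.ir_regions is not None:
            (a1, a2), (b1, b2) = self.ir_regions
            ira = self.sequence[a1 - 1 : a2]
            irb = self.sequence[b1 - 1 : b2]
            if irb != revcomp(ira):
                raise ValueError(
                    "ir_regions do not describe reverse-complementary intervals"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Read:
    """A sequencing read with per-base PHRED qualities and a platform tag."""

    id: str
    bases: str
    quals: list[int]
    platform: str = "illumina"
    mate: Optional[str] = None      # "first" | "second"
    pair_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases vs {len(self.quals)} qualities"
            )
        if any(q < 0 or q > 62 for q in self.quals):
            raise ValueError(f"read {self.id!r}: PHRED scores must lie in [0, 62]")

    def __len__(self) -> int:
        return len(self.bases)

    def error_probs(self) -> list[float]:
        return [phred_to_prob(q) for q in self.quals]


@dataclass
class ReadSet:
    """An ordered collection of reads (mates are adjacent when paired)."""

    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, i):
        return self.reads[i]

    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)

    def pairs_and_singles(self) -> list[list[Read]]:
        """Group reads into atomic units: mate pairs (by pair_id) or singles."""
        units: dict[str, list[Read]] = {}
        order: list[str] = []
        for idx, r in enumerate(self.reads):
            key = r.pair_id if r.pair_id is not None else f"__single_{idx}"
            if key not in units:
                units[key] = []
                order.append(key)
            units[key].append(r)
        return [units[k] for k in order]


@dataclass
class VariantTableRow:
    """One row of a two-platform variant table (Table-3-style layout).

    ``position`` is the 1-based reference coordinate (for insertions, the
    base immediately left of the anchor). ``"-"`` denotes an absent allele.
    For the rare site typed differently per platform the compound token
    ``"X/Y"`` records platform-A type X and platform-B type Y.
    """

    position: int
    type: str
    ref_allele: str
    allele_a: str
    allele_b: Optional[str] = None
    most_probable: Optional[str] = None

    def __post_init__(self) -> None:
        for t in self.type.split("/"):
            if t not in VARIANT_TYPES:
                raise FormatError(
                    f"unknown variant type {t!r}; accepted tokens: "
                    + ", ".join(VARIANT_TYPES)
                    + " (or a compound 'X/Y')"
                )
        if self.type == "ins" and self.ref_allele != "-":
            raise FormatError("insertions must have ref_allele '-'")
        if self.type == "del" and self.allele_a != "-" and self.allele_b is not None:
            # deletions: at least one platform (or the single alt column)
            # records the deleted allele as '-'
            if self.allele_b != "-":
                raise FormatError("deletion rows must carry a '-' alt allele")

    @property
    def anchor_label(self) -> str:
        if "ins" in self.type.split("/"):
            return f"{self.position}^{self.position + 1}"
        return str(self.position)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path, as_plastome: bool = True):
    """Read a FASTA file.

    Returns a single :class:`Plastome` when the file holds one record and
    ``as_plastome`` is true, otherwise a list of ``(id, sequence)`` tuples in
    file order. Lowercase input is uppercased; any non-A/C/G/T character is
    rejected with the offending record and position named.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(seq, 1) if c in bad)
            raise FormatError(
                f"{path}: record {rec.id!r} has non-ACGT character {seq[pos-1]!r} "
                f"at sequence position {pos}"
            )
        out.append((rec.id, seq))
    if as_plastome and len(out) == 1:
        rid, seq = out[0]
        return Plastome(id=rid, sequence=seq)
    return out


def write_fasta(path, records) -> None:
    """Write records (Plastome, (id, seq) tuples, or Contig-likes) as FASTA."""
    if isinstance(records, Plastome) or (
            isinstance(records, tuple) and len(records) == 2
            and all(isinstance(x, str) for x in records)):
        records = [records]
    seqrecs = []
    for rec in records:
        if isinstance(rec, Plastome):
            rid, seq = rec.id, rec.sequence
        elif isinstance(rec, tuple):
            rid, seq = rec
        else:  # duck-typed Contig
            rid, seq = rec.id, rec.sequence
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


def read_fastq(path, platform: str = "illumina") -> ReadSet:
    """Read a Sanger PHRED+33 FASTQ file into a :class:`ReadSet`.

    Mate membership is inferred from trailing ``/1`` ``/2`` id suffixes.
    """
    reads: list[Read] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            bases = str(rec.seq).upper()
            quals = list(rec.letter_annotations["phred_quality"])
            rid = rec.id
            mate = pair_id = None
            if rid.endswith("/1") or rid.endswith("/2"):
                mate = "first" if rid.endswith("/1") else "second"
                pair_id = rid[:-2]
            reads.append(Read(rid, bases, quals, platform=platform,
                              mate=mate, pair_id=pair_id))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return ReadSet(reads)


def write_fastq(path, reads: ReadSet) -> None:
    """Write a ReadSet as Sanger PHRED+33 FASTQ (LF line endings)."""
    with open(path, "w", newline="\n") as fh:
        for r in reads:
            qstr = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def read_variant_table(path) -> list[VariantTableRow]:
    """Read a TSV variant table.

    Accepts either the two-platform layout
    ``position  type  ref_allele  allele_a  allele_b [most_probable]``
    or the single-alt layout ``position  type  ref_allele  alt_allele``.
    A header line is required; ``-`` (or the typographic minus) marks an
    absent allele. Empty files yield an empty list.
    """
    rows: list[VariantTableRow] = []
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        return rows
    header = [h.strip().lower() for h in lines[0].split("\t")]
    required = {"position", "type", "ref_allele"}
    if not required <= set(header):
        raise FormatError(
            f"{path}: header must contain {sorted(required)}; got {header}"
        )
    idx = {name: header.index(name) for name in header}

    def norm(allele: str) -> str:
        allele = allele.strip().replace("−", "-").replace("–", "-")
        return allele if allele else "-"

    for lineno, ln in enumerate(lines[1:], 2):
        f = ln.split("\t")
        try:
            pos = int(f[idx["position"]].replace(",", "").split("^")[0])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad position {f[idx['position']]!r}") from exc
        vtype = f[idx["type"]].strip()
        ref = norm(f[idx["ref_allele"]])
        if "allele_a" in idx:
            a = norm(f[idx["allele_a"]])
            b = norm(f[idx["allele_b"]]) if "allele_b" in idx else None
        else:
            a = norm(f[idx["alt_allele"]])
            b = None
        mp = norm(f[idx["most_probable"]]) if "most_probable" in idx and len(f) > idx["most_probable"] else None
        rows.append(VariantTableRow(position=pos, type=vtype, ref_allele=ref,
                                    allele_a=a, allele_b=b, most_probable=mp))
    return rows


def write_variant_table(path, rows: Sequence[VariantTableRow]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("position\ttype\tref_allele\tallele_a\tallele_b\tmost_probable\n")
        for r in rows:
            fh.write(
                f"{r.position}\t{r.type}\t{r.ref_allele}\t{r.allele_a}\t"
                f"{r.allele_b if r.allele_b is not None else '-'}\t"
                f"{r.most_probable if r.most_probable is not None else ''}\n"
            )
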