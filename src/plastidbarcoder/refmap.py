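"""Reference mapping and majority-vote consensus extraction.

Reads are placed by seed-and-extend: exact k-mer seeds (default k = 15)
locate candidate diagonals, and a banded glocal dynamic program (read
aligned end-to-end, reference local) scores each candidate window under
the mapping cost model — mismatch 2, inserted base 3, deleted base 3.
Acceptance thresholds (length fraction and similarity fraction, both 0.9)
are applied after optimization. Reads with several equal-best placements
(typically inside the inverted repeat) are reported as multimapped and,
under the default policy, placed at one site chosen uniformly under a
fixed seed.

Consensus calling is by per-position majority vote of the covering reads:
the plurality symbol (base or deletion) wins; an insertion is emitted when
a plurality of the reads spanning the anchor support the same inserted
string; zero-depth positions emit the reference base and are flagged; ties
default to the reference allele.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from plastidbarcoder import _align
from plastidbarcoder.seq_io import Plastome, Read, ReadSet, revcomp

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_DEL_ROW = 4


@dataclass
class MappingParams:
    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    length_fraction: float = 0.9
    similarity_fraction: float = 0.9
    multimap_policy: str = "random"      # or "discard"
    k: int = 15
    band: int = 16
    seed: int = 0
    exhaustive_ref_len: int = 2000       # brute-force window for tiny references

    def __post_init__(self) -> None:
        if min(self.mismatch_cost, self.insertion_cost, self.deletion_cost) <= 0:
            raise ValueError("costs must be positive integers")
        for f in (self.length_fraction, self.similarity_fraction):
            if not 0.0 < f <= 1.0:
                raise ValueError("fractions must lie in (0, 1]")
        if self.multimap_policy not in ("random", "discard"):
            raise ValueError("multimap_policy must be 'random' or 'discard'")


@dataclass
class Alignment:
    read_id: str
    ref_id: str
    ref_start: int           # 1-based inclusive
    ref_end: int             # 1-based inclusive
    strand: str              # "+" | "-"
    ops: list[tuple[str, int]]
    cost: int
    identity: float
    query: str               # oriented read sequence as aligned
    n_diff: int = 0          # mismatched + inserted + deleted bases
    multimapped: bool = False

    @property
    def aligned_columns(self) -> int:
        return sum(ln for _op, ln in self.ops)


@dataclass
class MapResult:
    status: str                          # "mapped" | "unmapped" | "multimapped"
    alignment: Optional[Alignment] = None
    candidates: list[Alignment] = field(default_factory=list)
    reason: Optional[str] = None


@dataclass
class MappingReport:
    n_reads: int = 0
    n_mapped: int = 0
    n_multimapped: int = 0
    n_unmapped: int = 0
    mapped_fraction: float = 0.0
    mean_depth: float = 0.0
    width: float = 0.0


@dataclass
class ConsensusResult:
    """Per-position pileup tallies plus the voted consensus."""

    ref_id: str
    counts: np.ndarray                     # (5, L): A,C,G,T,deletion
    insertions: dict[int, Counter]         # anchor (1-based left pos) -> Counter
    insertion_spanning: dict[int, int]     # anchor -> reads spanning it
    consensus: str = ""
    depth: np.ndarray = None
    width: float = 0.0
    zero_coverage: list[int] = field(default_factory=list)
    ties: list[int] = field(default_factory=list)
    majority_deletions: list[int] = field(default_factory=list)
    majority_insertions: dict[int, str] = field(default_factory=dict)


class ReferenceIndex:
    """Exact k-mer index over one or more reference sequences."""

    def __init__(self, refs: Sequence[tuple[str, str]], k: int = 15):
        self.k = k
        self.refs = list(refs)
        self.index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ridx, (_rid, seq) in enumerate(self.refs):
            for i in range(len(seq) - k + 1):
                self.index[seq[i : i + k]].append((ridx, i))

    @staticmethod
    def from_reference(ref: Union[Plastome, Sequence], k: int = 15) -> "ReferenceIndex":
        if isinstance(ref, Plastome):
            return ReferenceIndex([(ref.id, ref.sequence)], k=k)
        return ReferenceIndex([(r.id, r.sequence) for r in ref], k=k)


def _candidate_windows(index: ReferenceIndex, bases: str, band: int):
    """Cluster seed hits into candidate (ref_idx, window) diagonals."""
    k = index.k
    m = len(bases)
    hits: dict[int, list[int]] = defaultdict(list)
    step = max(1, min(7, m - k + 1))
    for off in range(0, m - k + 1, step):
        km = bases[off : off + k]
        if "N" in km:
            continue
        for ridx, pos in index.index.get(km, ()):
            hits[ridx].append(pos - off)
    out = []
    for ridx, diags in hits.items():
        diags.sort()
        group = [diags[0]]
        for d in diags[1:]:
            if d - group[-1] <= band:
                group.append(d)
            else:
                out.append((ridx, group[0], group[-1]))
                group = [d]
        out.append((ridx, group[0], group[-1]))
    return out


def _ungapped_candidate(bases: str, refseq: str, dlo: int, dhi: int,
                        params: MappingParams):
    """Best ungapped placement on the cluster's diagonals.

    An ungapped cost of at most ``min(insertion_cost, deletion_cost) - 1``
    cannot be beaten by any gapped alignment, so the banded DP is skipped
    for (near-)perfect reads."""
    m = len(bases)
    enc = np.frombuffer(bases.encode(), dtype=np.uint8)
    best = None
    for d in range(dlo, dhi + 1):
        if d < 0 or d + m > len(refseq):
            continue
        seg = np.frombuffer(refseq[d : d + m].encode(), dtype=np.uint8)
        mm = int(np.count_nonzero(seg != enc))
        if best is None or mm < best[1]:
            best = (d, mm)
    if best is None:
        return None
    d, mm = best
    cost = params.mismatch_cost * mm
    if cost >= min(params.insertion_cost, params.deletion_cost):
        return None
    if mm == 0:
        ops = [("=", m)]
    else:
        ops = _align._rle(["=" if a == b else "X"
                           for a, b in zip(bases, refseq[d : d + m])])
    return d, cost, ops


def _align_window(bases: str, ridx: int, wstart: int, wend: int,
                  index: ReferenceIndex, params: MappingParams,
                  strand: str, read_id: str) -> Alignment:
    rid, refseq = index.refs[ridx]
    window = refseq[wstart:wend]
    cost, s, e, ops = _align.glocal_align(
        bases, window, mismatch=params.mismatch_cost,
        ins_cost=params.insertion_cost, del_cost=params.deletion_cost,
    )
    matches = sum(ln for op, ln in ops if op == "=")
    cols = sum(ln for _op, ln in ops)
    ndiff = sum(ln for op, ln in ops if op != "=")
    return Alignment(
        read_id=read_id, ref_id=rid, ref_start=wstart + s + 1,
        ref_end=wstart + e, strand=strand, ops=ops, cost=cost,
        identity=matches / cols if cols else 0.0, query=bases, n_diff=ndiff,
    )


def map_read(read: Read, ref, params: Optional[MappingParams] = None,
             index: Optional[ReferenceIndex] = None) -> MapResult:
    """Map one (trimmed) read; returns mapped/unmapped/multimapped.

    A minimum-cost placement under the cost model is sought over both
    strands; equal-best placements are reported as multimapped.
    """
    params = params or MappingParams()
    if index is None:
        index = ReferenceIndex.from_reference(ref, k=params.k)
    m = len(read)
    if m < index.k:
        return MapResult("unmapped", reason="shorter than seed length")
    total_ref = sum(len(s) for _i, s in index.refs)
    candidates: list[Alignment] = []
    for strand, bases in (("+", read.bases), ("-", revcomp(read.bases))):
        windows = _candidate_windows(index, bases, params.band)
        if not windows and total_ref <= params.exhaustive_ref_len:
            windows = [(ridx, 0, len(seq) - m)
                       for ridx, (_r, seq) in enumerate(index.refs)]
        for ridx, dlo, dhi in windows:
            rid, refseq = index.refs[ridx]
            fast = _ungapped_candidate(bases, refseq, dlo, dhi, params)
            if fast is not None:
                d, cost, ops = fast
                matches = sum(ln for op, ln in ops if op == "=")
                candidates.append(Alignment(
                    read_id=read.id, ref_id=rid, ref_start=d + 1,
                    ref_end=d + m, strand=strand, ops=ops, cost=cost,
                    identity=matches / m, query=bases, n_diff=m - matches,
                ))
                continue
            ws = max(0, dlo - params.band)
            we = min(len(refseq), dhi + m + params.band)
            if we <= ws:
                continue
            candidates.append(_align_window(bases, ridx, ws, we, index,
                                            params, strand, read.id))
    if not candidates:
        return MapResult("unmapped", reason="no seed match")
    best_cost = min(a.cost for a in candidates)
    best: dict[tuple, Alignment] = {}
    for a in candidates:
        if a.cost == best_cost:
            key = (a.ref_id, a.strand, a.ref_start)
            best.setdefault(key, a)
    winners = list(best.values())
    a0 = winners[0]
    # acceptance thresholds, applied after optimization
    aligned_read = sum(ln for op, ln in a0.ops if op in "=XI")
    if aligned_read < params.length_fraction * m:
        return MapResult("unmapped", reason="below length fraction")
    if a0.identity < params.similarity_fraction:
        return MapResult("unmapped", reason="below similarity fraction")
    if len(winners) == 1:
        return MapResult("mapped", alignment=a0)
    for w in winners:
        w.multimapped = True
    return MapResult("multimapped", candidates=winners)


def map_reads(reads: ReadSet, ref, params: Optional[MappingParams] = None
              ) -> tuple[list[Alignment], MappingReport]:
    """Map a read set; multimapped reads are placed by seeded uniform
    choice among equal-best sites (policy "random") or dropped."""
    params = params or MappingParams()
    index = ReferenceIndex.from_reference(ref, k=params.k)
    rng = np.random.default_rng(params.seed)
    alignments: list[Alignment] = []
    report = MappingReport(n_reads=len(reads))
    for read in reads:
        res = map_read(read, ref, params, index=index)
        if res.status == "mapped":
            alignments.append(res.alignment)
            report.n_mapped += 1
        elif res.status == "multimapped":
            report.n_multimapped += 1
            if params.multimap_policy == "random":
                alignments.append(res.candidates[int(rng.integers(len(res.candidates)))])
                report.n_mapped += 1
        else:
            report.n_unmapped += 1
    report.mapped_fraction = report.n_mapped / len(reads) if len(reads) else 0.0
    if alignments:
        total_len = sum(len(s) for _i, s in index.refs)
        cov = np.zeros(total_len, dtype=np.int64)
        offsets = {}
        off = 0
        for rid, seq in index.refs:
            offsets[rid] = off
            off += len(seq)
        for a in alignments:
            o = offsets[a.ref_id]
            cov[o + a.ref_start - 1 : o + a.ref_end] += 1
        report.mean_depth = float(cov.mean())
        report.width = float((cov > 0).mean())
    return alignments, report


# ---------------------------------------------------------------------------
# Pileup and consensus
# ---------------------------------------------------------------------------

def build_pileup(alignments: Sequence[Alignment], ref) -> ConsensusResult:
    """Tally every aligned base, deletion and anchored insertion once."""
    refseq = ref.sequence if isinstance(ref, Plastome) else ref
    rid = ref.id if isinstance(ref, Plastome) else "ref"
    L = len(refseq)
    counts = np.zeros((5, L), dtype=np.int32)
    insertions: dict[int, Counter] = defaultdict(Counter)
    for a in alignments:
        if a.ref_start < 1 or a.ref_end > L:
            raise ValueError(
                f"alignment of {a.read_id} at {a.ref_start}..{a.ref_end} "
                f"outside reference of length {L}"
            )
        rpos = a.ref_start - 1
        qpos = 0
        for op, ln in a.ops:
            if op in "=X":
                for t in range(ln):
                    c = _CODE.get(a.query[qpos + t])
                    if c is not None:
                        counts[c, rpos + t] += 1
                rpos += ln
                qpos += ln
            elif op == "D":
                counts[_DEL_ROW, rpos : rpos + ln] += 1
                rpos += ln
            else:  # I
                insertions[rpos][a.query[qpos : qpos + ln]] += 1
                qpos += ln
    spanning: dict[int, int] = {}
    if insertions:
        starts = np.array([a.ref_start for a in alignments])
        ends = np.array([a.ref_end for a in alignments])
        for anchor in insertions:
            spanning[anchor] = int(np.count_nonzero(
                (starts <= anchor) & (ends >= anchor + 1)))
    depth = counts.sum(axis=0)
    return ConsensusResult(
        ref_id=rid, counts=counts, insertions=dict(insertions),
        insertion_spanning=spanning, depth=depth,
        width=float((depth > 0).mean()) if L else 0.0,
    )


def call_consensus(pileup: ConsensusResult, ref,
                   tie_policy: str = "reference") -> ConsensusResult:
    """Fill the consensus by per-position plurality vote.

    Majority deletions remove the position; a majority insertion (plurality
    of spanning reads supporting the identical inserted string, reads only
    partially overlapping the anchor excluded from the vote) is emitted
    after its anchor; zero-depth positions emit the reference base and are
    flagged; ties resolve to the reference allele (logged).
    """
    refseq = ref.sequence if isinstance(ref, Plastome) else ref
    L = len(refseq)
    counts = pileup.counts
    depth = pileup.depth
    maxc = counts.max(axis=0)
    winner = counts.argmax(axis=0)
    n_at_max = (counts == maxc[None, :]).sum(axis=0)
    tie_pos = np.nonzero((n_at_max > 1) & (depth > 0))[0]
    symbols = "ACGT-"
    ref_codes = np.fromiter((_CODE.get(c, 0) for c in refseq), dtype=np.int64,
                            count=L)
    for p in tie_pos:
        tied = np.nonzero(counts[:, p] == maxc[p])[0]
        if tie_policy == "reference" and ref_codes[p] in tied:
            winner[p] = ref_codes[p]
        else:
            winner[p] = tied[0]
    pileup.ties = [int(p) + 1 for p in tie_pos]
    if pileup.ties:
        logger.info("%d voting ties resolved by %s policy",
                    len(pileup.ties), tie_policy)

    # insertion votes
    maj_ins: dict[int, str] = {}
    for anchor, cnt in pileup.insertions.items():
        span = pileup.insertion_spanning.get(anchor, 0)
        total_ins = sum(cnt.values())
        no_ins = max(span - total_ins, 0)
        (top_seq, top_n), = cnt.most_common(1)
        others = max([n for s, n in cnt.items() if s != top_seq], default=0)
        if top_n > no_ins and top_n > others:
            maj_ins[anchor] = top_seq

    out: list[str] = []
    zero_cov: list[int] = []
    maj_del: list[int] = []
    if 0 in maj_ins:
        out.append(maj_ins[0])
    for p in range(L):
        if depth[p] == 0:
            zero_cov.append(p + 1)
            out.append(refseq[p])
        elif winner[p] == _DEL_ROW:
            maj_del.append(p + 1)
        else:
            out.append(symbols[winner[p]])
        if (p + 1) in maj_ins:
            out.append(maj_ins[p + 1])
    pileup.consensus = "".join(out)
    pileup.zero_coverage = zero_cov
    pileup.majority_deletions = maj_del
    pileup.majority_insertions = maj_ins
    if zero_cov:
        logger.warning("%d zero-coverage positions emitted as reference",
                       len(zero_cov))
    return pileup
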