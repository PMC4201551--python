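"""De novo assembly and contig-to-reference scaffolding.

The assembler is a plain de Bruijn graph over read k-mers (both strands),
with a coverage floor that drops singleton k-mers, tip clipping (dead-end
paths shorter than 2k), and coverage-weighted bubble popping. Unbranched
paths are emitted as contigs. A reference-guided mode biases bubble
resolution toward branches whose k-mers occur in the reference — an
approximation of reference-assisted assembly; contigs remain strictly
read-derived.

Contigs are placed on the reference NUCmer-style: exact 20-mer anchors are
clustered by diagonal, each cluster is extended with a semi-global
alignment, and — because a plastome carries two inverted repeats — all
matches are reported regardless of uniqueness when requested. Scaffold
selection automates the manual joining step with an explicit lexicographic
rule: candidates ranked by (aligned length, percent identity, query
coverage), tiled along the reference, merged across sequence overlaps of
at least ``min_overlap`` bases at >= 95% identity. Any uncovered reference
interval yields a gap report instead of a consensus.
"""

from __future__ import annotations

import logging
import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from plastidbarcoder import refmap as _refmap
from plastidbarcoder.seq_io import Plastome, ReadSet, revcomp

logger = logging.getLogger(__name__)


class AssemblyError(RuntimeError):
    pass


class JoinConflictError(AssemblyError):
    """Selected contigs disagree in their overlap beyond tolerance."""


@dataclass
class AssemblyParams:
    k: Optional[int] = None              # None = auto from genome-size proxy
    bubble_size: int = 50
    min_contig_length: int = 200
    reference_guided: bool = False
    min_kmer_count: int = 2              # absolute coverage floor; singletons dropped
    relative_floor: float = 0.2          # floor as a fraction of median k-mer depth
    assumed_coverage: float = 50.0       # for the auto-k genome-size proxy

    def resolve_k(self, total_bases: int) -> int:
        if self.k is not None:
            k = self.k
        else:
            proxy = max(total_bases / self.assumed_coverage, 4.0)
            k = round(math.log(proxy, 4))
            k = min(max(k, 15), 31)
        if k % 2 == 0:
            k += 1
        return k


@dataclass
class Contig:
    id: str
    sequence: str
    mean_depth: float = 0.0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ScaffoldAlignment:
    contig_id: str
    ref_start: int              # 1-based inclusive
    ref_end: int
    strand: str
    query_coverage: float
    percent_identity: float
    aligned_length: int
    unique: bool = True


@dataclass
class GapReport:
    gaps: list[tuple[int, int]] = field(default_factory=list)
    junction_failures: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class JoinResult:
    consensus: Optional[str] = None
    gap_report: Optional[GapReport] = None
    tiling: list[tuple[str, int, int]] = field(default_factory=list)
    span: Optional[tuple[int, int]] = None   # reference interval the consensus covers

    @property
    def joined(self) -> bool:
        return self.consensus is not None


# ---------------------------------------------------------------------------
# De Bruijn assembly
# ---------------------------------------------------------------------------

def _count_kmers(reads: ReadSet, k: int) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for r in reads:
        for s in (r.bases, revcomp(r.bases)):
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                if "N" not in km:
                    counts[km] += 1
    return counts


class _Graph:
    def __init__(self, kmers: dict[str, int], k: int):
        self.k = k
        self.kmers = kmers
        self.rebuild()

    def rebuild(self) -> None:
        self.out: dict[str, list[str]] = defaultdict(list)
        self.indeg: dict[str, int] = defaultdict(int)
        for km in self.kmers:
            self.out[km[:-1]].append(km[-1])
            self.indeg[km[1:]] += 1
        for node in self.out:
            self.out[node].sort()

    def outdeg(self, node: str) -> int:
        return len(self.out.get(node, ()))

    def unitigs(self) -> list[tuple[str, float]]:
        """Maximal unbranched paths with mean k-mer coverage."""
        k = self.k
        visited: set[str] = set()
        tigs: list[tuple[str, float]] = []

        def walk(km: str) -> tuple[str, float]:
            visited.add(km)
            seq = [km]
            covs = [self.kmers[km]]
            node = km[1:]
            while self.indeg.get(node, 0) == 1 and self.outdeg(node) == 1:
                nxt = node + self.out[node][0]
                if nxt in visited or nxt not in self.kmers:
                    break
                visited.add(nxt)
                seq.append(nxt[-1])
                covs.append(self.kmers[nxt])
                node = nxt[1:]
            return "".join(seq), float(np.mean(covs))

        starts = []
        for km in self.kmers:
            pre = km[:-1]
            if self.indeg.get(pre, 0) != 1 or self.outdeg(pre) != 1:
                starts.append(km)
        for km in sorted(starts):
            if km not in visited:
                tigs.append(walk(km))
        for km in sorted(self.kmers):  # isolated cycles
            if km not in visited:
                tigs.append(walk(km))
        return tigs

    def drop_path_kmers(self, seq: str) -> None:
        k = self.k
        for i in range(len(seq) - k + 1):
            self.kmers.pop(seq[i : i + k], None)

    def clip_tips(self, max_len: int) -> int:
        """Remove dead-end unbranched paths shorter than max_len that hang
        off a branch."""
        removed = 0
        for seq, _cov in self.unitigs():
            if len(seq) >= max_len:
                continue
            k = self.k
            first, last = seq[: k - 1], seq[-(k - 1):]
            dead_start = self.indeg.get(first, 0) == 0
            dead_end = self.outdeg(last) == 0
            if dead_start != dead_end:  # a tip hangs off exactly one branch
                self.drop_path_kmers(seq)
                removed += 1
        if removed:
            self.rebuild()
        return removed

    def pop_bubbles(self, bubble_size: int,
                    ref_kmers: Optional[set[str]] = None) -> int:
        removed = 0
        k = self.k
        for node in sorted(self.out):
            bases = self.out.get(node, [])
            if len(bases) != 2:
                continue
            paths = []
            ok = True
            for b in bases:
                km = node + b
                if km not in self.kmers:
                    ok = False
                    break
                seq = km
                covs = [self.kmers[km]]
                cur = km[1:]
                while (self.outdeg(cur) == 1 and self.indeg.get(cur, 0) == 1
                       and len(seq) < k + bubble_size):
                    nxt = cur + self.out[cur][0]
                    seq += nxt[-1]
                    covs.append(self.kmers.get(nxt, 0))
                    cur = nxt[1:]
                paths.append((seq, cur, float(np.mean(covs))))
            if not ok or paths[0][1] != paths[1][1]:
                continue
            c0, c1 = paths[0][2], paths[1][2]
            loser = 0 if c0 < c1 else 1
            if ref_kmers is not None and min(c0, c1) >= 0.8 * max(c0, c1):
                in_ref = [sum(1 for i in range(len(p[0]) - k + 1)
                              if p[0][i : i + k] in ref_kmers)
                          for p in paths]
                if in_ref[0] != in_ref[1]:
                    loser = 0 if in_ref[0] < in_ref[1] else 1
            self.drop_path_kmers(paths[loser][0])
            removed += 1
        if removed:
            self.rebuild()
        return removed


def assemble(reads: ReadSet, params: Optional[AssemblyParams] = None,
             ref: Optional[Plastome] = None) -> list[Contig]:
    """Assemble reads into contigs (deterministic given the read set)."""
    params = params or AssemblyParams()
    k = params.resolve_k(reads.total_bases())
    raw = _count_kmers(reads, k)
    floor = params.min_kmer_count
    if raw and params.relative_floor > 0:
        # depth-weighted median: the k-mer depth a typical sequenced base
        # sits at, robust to the long tail of low-count error k-mers
        arr = np.sort(np.fromiter(raw.values(), dtype=np.int64))
        cum = np.cumsum(arr)
        wmed = float(arr[np.searchsorted(cum, cum[-1] / 2)])
        floor = max(floor, int(round(params.relative_floor * wmed)))
    counts = {km: c for km, c in raw.items() if c >= floor}
    if not counts:
        logger.warning("no k-mer passed the coverage floor (k=%d)", k)
        return []
    graph = _Graph(counts, k)
    ref_kmers: Optional[set[str]] = None
    if params.reference_guided and ref is not None:
        seq = ref.sequence
        ref_kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        ref_kmers |= {revcomp(km) for km in ref_kmers}
    for _round in range(4):
        changed = graph.clip_tips(2 * k)
        changed += graph.pop_bubbles(params.bubble_size, ref_kmers)
        if not changed:
            break
    # emit, deduplicating reverse-complement twins
    seen: set[str] = set()
    tigs = []
    for seq, cov in graph.unitigs():
        if len(seq) < params.min_contig_length:
            continue
        canon = min(seq, revcomp(seq))
        if canon in seen:
            continue
        seen.add(canon)
        tigs.append((seq, cov))
    tigs.sort(key=lambda t: (-len(t[0]), t[0]))
    return [Contig(id=f"contig_{i + 1}", sequence=seq, mean_depth=cov)
            for i, (seq, cov) in enumerate(tigs)]


# ---------------------------------------------------------------------------
# Polishing
# ---------------------------------------------------------------------------

def polish_contigs(contigs: Sequence[Contig], reads: ReadSet,
                   mapping_params: Optional[_refmap.MappingParams] = None,
                   max_iterations: int = 3) -> list[Contig]:
    """Map reads back to the contigs and replace each contig by its
    majority consensus; iterate to convergence (at most 3 rounds).
    Contigs attracting no reads are left unchanged."""
    params = mapping_params or _refmap.MappingParams()
    current = [Contig(c.id, c.sequence, c.mean_depth) for c in contigs]
    for _it in range(max_iterations):
        alignments, _rep = _refmap.map_reads(ReadSet(list(reads.reads)),
                                             current, params)
        by_ref: dict[str, list] = defaultdict(list)
        for a in alignments:
            by_ref[a.ref_id].append(a)
        changed = False
        polished: list[Contig] = []
        for c in current:
            alns = by_ref.get(c.id)
            if not alns:
                logger.info("contig %s attracted no reads; left unchanged", c.id)
                polished.append(c)
                continue
            pile = _refmap.build_pileup(alns, Plastome(c.id, c.sequence))
            res = _refmap.call_consensus(pile, Plastome(c.id, c.sequence))
            if res.consensus != c.sequence:
                changed = True
            polished.append(Contig(c.id, res.consensus, c.mean_depth))
        current = polished
        if not changed:
            break
    return current


# ---------------------------------------------------------------------------
# Contig-to-reference alignment and joining
# ---------------------------------------------------------------------------

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matching columns, total columns) from an edlib extended cigar."""
    match = total = 0
    for ln, op in _CIG_RE.findall(cigar):
        ln = int(ln)
        total += ln
        if op == "=":
            match += ln
    return match, total


def align_contigs(contigs: Sequence[Contig], ref: Plastome,
                  allow_nonunique: bool = True, anchor_k: int = 20,
                  min_anchors: int = 3, min_identity: float = 0.8
                  ) -> list[ScaffoldAlignment]:
    """Place contigs on the reference by exact-anchor clustering plus
    semi-global extension; a contig matching both inverted-repeat copies
    yields two alignments when ``allow_nonunique``."""
    refseq = ref.sequence
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(refseq) - anchor_k + 1):
        index[refseq[i : i + anchor_k]].append(i)
    out: list[ScaffoldAlignment] = []
    for c in contigs:
        placements = []
        for strand, seq in (("+", c.sequence), ("-", revcomp(c.sequence))):
            hits: list[int] = []
            step = max(1, anchor_k // 2)
            for off in range(0, len(seq) - anchor_k + 1, step):
                for pos in index.get(seq[off : off + anchor_k], ()):
                    hits.append(pos - off)
            if not hits:
                continue
            hits.sort()
            clusters: list[list[int]] = [[hits[0]]]
            for d in hits[1:]:
                if d - clusters[-1][-1] <= 200:
                    clusters[-1].append(d)
                else:
                    clusters.append([d])
            for cl in clusters:
                if len(cl) < min_anchors:
                    continue
                ws = max(0, cl[0] - 100)
                we = min(len(refseq), cl[-1] + len(seq) + 100)
                res = edlib.align(seq, refseq[ws:we], mode="HW", task="path")
                if res["editDistance"] < 0:
                    continue
                s, e = res["locations"][0]
                matches, cols = _cigar_stats(res["cigar"])
                ident = matches / cols if cols else 0.0
                if ident < min_identity:
                    continue
                placements.append(ScaffoldAlignment(
                    contig_id=c.id, ref_start=ws + s + 1, ref_end=ws + e + 1,
                    strand=strand, query_coverage=1.0,
                    percent_identity=ident, aligned_length=e - s + 1,
                ))
        # deduplicate placements landing on the same interval
        dedup: dict[tuple[int, str], ScaffoldAlignment] = {}
        for p in placements:
            key = (p.ref_start // 50, p.strand)
            prev = dedup.get(key)
            if prev is None or p.percent_identity > prev.percent_identity:
                dedup[key] = p
        placements = sorted(dedup.values(),
                            key=lambda p: (-p.percent_identity, p.ref_start))
        if not placements:
            continue
        if not allow_nonunique:
            placements = placements[:1]
        for p in placements:
            p.unique = len(placements) == 1
        out.extend(placements)
    out.sort(key=lambda p: (p.ref_start, p.contig_id))
    return out


def join_contigs(alignments: Sequence[ScaffoldAlignment],
                 contigs: Sequence[Contig], ref: Plastome,
                 min_overlap: int = 20, overlap_identity: float = 0.95,
                 end_tolerance: int = 100) -> JoinResult:
    """Tile selected contigs along the reference and join them.

    Candidates are ranked by (aligned length, identity, query coverage)
    descending; a candidate is selected when it covers reference positions
    not yet covered. Adjacent selections need a sequence overlap of at
    least ``min_overlap`` bases and are spliced at an exact junction
    anchor shared by both contig ends; any uncovered INTERNAL reference
    interval yields a :class:`GapReport` instead of a consensus, and an
    overlap with no clean junction raises
    :class:`JoinConflictError`. Uncovered stretches touching the
    reference ends and no longer than ``end_tolerance`` are tolerated (a
    linear assembly loses its terminal k-mers to the coverage floor): the
    consensus then spans the covered interval, reported in ``span``.
    """
    by_id = {c.id: c for c in contigs}
    L = len(ref.sequence)
    covered = np.zeros(L + 1, dtype=bool)
    ranked = sorted(alignments, key=lambda a: (-a.aligned_length,
                                               -a.percent_identity,
                                               -a.query_coverage))
    selected: list[ScaffoldAlignment] = []
    for a in ranked:
        span = covered[a.ref_start : a.ref_end + 1]
        if not span.all():
            covered[a.ref_start : a.ref_end + 1] = True
            selected.append(a)
    report = GapReport()
    uncovered = ~covered[1:]
    if uncovered.any():
        idx = np.nonzero(uncovered)[0] + 1
        start = prev = int(idx[0])
        runs = []
        for p in idx[1:]:
            p = int(p)
            if p != prev + 1:
                runs.append((start, prev))
                start = p
            prev = p
        runs.append((start, prev))
        for s, e in runs:
            terminal = (s == 1 or e == L) and (e - s + 1) <= end_tolerance
            if not terminal:
                report.gaps.append((s, e))

    selected.sort(key=lambda a: a.ref_start)
    pieces: list[tuple[ScaffoldAlignment, str]] = []
    for a in selected:
        seq = by_id[a.contig_id].sequence
        pieces.append((a, seq if a.strand == "+" else revcomp(seq)))

    if report.gaps:
        return JoinResult(gap_report=report,
                          tiling=[(a.contig_id, a.ref_start, a.ref_end)
                                  for a in selected])

    out = pieces[0][1]
    cur_end = pieces[0][0].ref_end
    for a, seq in pieces[1:]:
        if a.ref_end <= cur_end:
            continue  # fully contained after tiling
        overlap = cur_end - a.ref_start + 1
        if overlap < min_overlap:
            report.junction_failures.append((a.ref_start, cur_end))
            return JoinResult(gap_report=report,
                              tiling=[(x.contig_id, x.ref_start, x.ref_end)
                                      for x in selected])
        # Splice at a 12-mer of the reference overlap that occurs exactly
        # once in both contig ends: the shared exact anchor guarantees a
        # seamless junction even when one contig end carries a local
        # artifact (contig ends are the least reliable assembly stretch).
        window = out[-min(len(out), overlap + 60):]
        head_region = seq[: overlap + 60]
        half = 6
        lo = a.ref_start - 1 + half          # 0-based candidate cut range
        hi = cur_end - half
        mid = (lo + hi) // 2
        merged = None
        for refcut in sorted(range(lo, hi), key=lambda r: abs(r - mid)):
            kmer = ref.sequence[refcut - half : refcut + half]
            if window.count(kmer) == 1 and head_region.count(kmer) == 1:
                i = window.index(kmer)
                j = head_region.index(kmer)
                merged = out[: len(out) - len(window) + i] + seq[j:]
                break
        if merged is None:
            raise JoinConflictError(
                f"contigs disagree in overlap near reference interval "
                f"{a.ref_start}..{cur_end} (no shared exact junction anchor)"
            )
        out = merged
        cur_end = a.ref_end
    return JoinResult(consensus=out,
                      tiling=[(a.contig_id, a.ref_start, a.ref_end)
                              for a in selected],
                      span=(selected[0].ref_start, cur_end))
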