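"""Synthetic plastomes, truth variant sets, and platform-specific reads.

The generator emulates the features of a chloroplast genome that drive the
pipeline's behaviour: AT-rich composition (GC ~= 39%), a pair of long
inverted repeats, and a heavy-tailed homopolymer-run spectrum (runs of up
to 17 identical bases, with the long runs almost exclusively A/T — real
plastomes top out near 9 bp for G/C runs). Reads are simulated under two
presets: an Illumina-like paired-end model (substitution errors only,
rate ~0.1%) and an Ion-Torrent-like single-read model (~1% total error
dominated by homopolymer indels: deletions concentrated in short 2-5 bp
G/C runs, insertions in long >=5 bp A/T runs).

Error placement: substitutions are per-base Bernoulli; homopolymer indels
are per-run Bernoulli with rate f(base class, run length), at most one
event per run per read. Base qualities are drawn from a platform preset
independently of whether a base is erroneous — trimming operates on
claimed, not true, quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from plastidbarcoder.seq_io import Plastome, Read, ReadSet, revcomp
from plastidbarcoder.variants import Variant, apply_variants, left_normalize

BASES = "ACGT"
AT = "AT"
GC = "GC"

# default homopolymer run-length weight tables (relative, per class);
# G/C runs top out at 9 bases, A/T runs carry a boosted tail up to 17
_GC_RUN_WEIGHTS = {L: 0.36 ** (L - 1) for L in range(1, 10)}
_AT_RUN_WEIGHTS = {L: 0.42 ** (L - 1) for L in range(1, 18)}
for _L in range(5, 18):
    _AT_RUN_WEIGHTS[_L] += 0.004 * 0.72 ** (_L - 5)


@dataclass
class GenomeSpec:
    length: int = 130_000
    gc_fraction: float = 0.39
    ir_length: int = 20_000          # 0 disables the inverted repeat
    homopolymer_boost: Optional[dict[int, float]] = None  # extra AT-run weight
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1_000:
            raise ValueError("genome length must be >= 1000")
        if self.ir_length and 2 * self.ir_length >= self.length:
            raise ValueError("2*ir_length must be smaller than the genome")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")


@dataclass
class VariantSpec:
    n_snp: int = 92
    n_mnv: int = 5
    n_ins: int = 13
    n_del: int = 18
    indel_length_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.62, 2: 0.18, 3: 0.1, 4: 0.05, 12: 0.025, 13: 0.025}
    )
    homopolymer_targeting_fraction: float = 0.5
    min_spacing: int = 30
    avoid_ir: bool = True
    seed: int = 0


@dataclass
class ErrorModel:
    """Platform error profile used by :func:`simulate_reads`.

    Besides the random per-read components (substitutions, per-run
    homopolymer indels), the model supports SYSTEMATIC homopolymer sites:
    a small fraction of genome runs is designated "hot" (deterministically
    under the simulation seed), and most reads covering a hot run carry
    the same indel. These are the loci that survive majority voting and
    surface as consensus-level platform errors — the mechanism behind
    cross-platform discrepancies at homopolymers.
    """

    platform: str
    substitution_rate: float
    hp_deletion_rate: Callable[[str, int], float]
    hp_insertion_rate: Callable[[str, int], float]
    read_length: int
    paired: bool = False
    insert_mean: float = 550.0
    insert_sd: float = 50.0
    mean_q: float = 30.0
    sd_q: float = 4.0
    # probability that a genome run of (class, length) is a systematic
    # error site, and the per-read error rate at such a site
    systematic_del_prob: Callable[[str, int], float] = lambda cls, ln: 0.0
    systematic_ins_prob: Callable[[str, int], float] = lambda cls, ln: 0.0
    systematic_error_rate: float = 0.85

    @staticmethod
    def illumina(read_length: int = 100, paired: bool = True,
                 substitution_rate: float = 0.001) -> "ErrorModel":
        """Substitution-only paired-end preset (error rate >= 0.1%)."""
        zero = lambda cls, ln: 0.0
        return ErrorModel(
            platform="illumina", substitution_rate=substitution_rate,
            hp_deletion_rate=zero, hp_insertion_rate=zero,
            read_length=read_length, paired=paired,
            insert_mean=550.0, insert_sd=50.0, mean_q=30.5, sd_q=4.0,
        )

    @staticmethod
    def iontorrent(read_length: int = 200,
                   substitution_rate: float = 0.002,
                   systematic: bool = True) -> "ErrorModel":
        """Semiconductor single-read preset: ~1% total error, indels
        dominant; deletions peak in short G/C runs, insertions in long
        A/T runs. ``systematic`` enables consensus-level error sites."""

        def del_rate(cls: str, ln: int) -> float:
            if cls == "GC":
                return {1: 0.0003, 2: 0.030, 3: 0.075, 4: 0.060, 5: 0.050}.get(
                    ln, 0.012
                )
            return {1: 0.0002}.get(ln, 0.008)

        def ins_rate(cls: str, ln: int) -> float:
            if cls == "AT" and ln >= 5:
                return min(0.04 + 0.02 * (ln - 5), 0.2)
            return 0.0005

        def sys_del(cls: str, ln: int) -> float:
            if not systematic:
                return 0.0
            if 2 <= ln <= 5:
                return 0.005 if cls == "GC" else 0.0015
            return 0.0

        def sys_ins(cls: str, ln: int) -> float:
            if not systematic:
                return 0.0
            return 0.008 if (cls == "AT" and ln >= 5) else 0.0

        return ErrorModel(
            platform="iontorrent", substitution_rate=substitution_rate,
            hp_deletion_rate=del_rate, hp_insertion_rate=ins_rate,
            read_length=read_length, paired=False, mean_q=25.5, sd_q=4.0,
            systematic_del_prob=sys_del, systematic_ins_prob=sys_ins,
        )


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _sample_runs(rng: np.random.Generator, n_bases: int, gc_fraction: float,
                 at_weights: dict[int, float], gc_weights: dict[int, float],
                 prev_base: str = "") -> str:
    at_l = np.array(sorted(at_weights))
    at_w = np.array([at_weights[L] for L in at_l], dtype=float)
    at_w /= at_w.sum()
    gc_l = np.array(sorted(gc_weights))
    gc_w = np.array([gc_weights[L] for L in gc_l], dtype=float)
    gc_w /= gc_w.sum()
    mean_at = float((at_l * at_w).sum())
    mean_gc = float((gc_l * gc_w).sum())
    # pick run-class probability so expected base composition hits the target
    g = gc_fraction
    p_gc = (g / mean_gc) / (g / mean_gc + (1 - g) / mean_at) if 0 < g < 1 else g
    parts: list[str] = []
    total = 0
    prev = prev_base
    while total < n_bases:
        if rng.random() < p_gc:
            cls, lens, w = GC, gc_l, gc_w
        else:
            cls, lens, w = AT, at_l, at_w
        choices = [b for b in cls if b != prev]
        base = choices[rng.integers(len(choices))]
        ln = int(rng.choice(lens, p=w))
        parts.append(base * ln)
        total += ln
        prev = base
    return "".join(parts)[:n_bases]


def generate_plastome(spec: GenomeSpec) -> Plastome:
    """Generate a plastome-like truth genome, deterministic under seed.

    Layout with an inverted repeat: LSC + IRa + SSC + IRb where IRb is the
    reverse complement of IRa (the quadripartite plastome structure).
    """
    rng = np.random.default_rng(spec.seed)
    at_w = dict(_AT_RUN_WEIGHTS)
    if spec.homopolymer_boost:
        for L, w in spec.homopolymer_boost.items():
            at_w[L] = at_w.get(L, 0.0) + w
    if spec.ir_length == 0:
        seq = _sample_runs(rng, spec.length, spec.gc_fraction, at_w, _GC_RUN_WEIGHTS)
        return Plastome(id=f"synthetic_plastome_{spec.seed}", sequence=seq)
    single = spec.length - 2 * spec.ir_length
    l1 = round(0.8 * single)  # large single-copy region
    l2 = single - l1
    lsc = _sample_runs(rng, l1, spec.gc_fraction, at_w, _GC_RUN_WEIGHTS)
    ira = _sample_runs(rng, spec.ir_length, spec.gc_fraction, at_w,
                       _GC_RUN_WEIGHTS, prev_base=lsc[-1])
    ssc = _sample_runs(rng, l2, spec.gc_fraction, at_w, _GC_RUN_WEIGHTS,
                       prev_base=ira[-1])
    seq = lsc + ira + ssc + revcomp(ira)
    ir_regions = (
        (l1 + 1, l1 + spec.ir_length),
        (l1 + spec.ir_length + l2 + 1, len(seq)),
    )
    return Plastome(id=f"synthetic_plastome_{spec.seed}", sequence=seq,
                    ir_regions=ir_regions)


# ---------------------------------------------------------------------------
# Truth variant implantation
# ---------------------------------------------------------------------------

def _allowed(pos: int, span: int, taken: list[tuple[int, int]],
             spacing: int, lo: int, hi: int) -> bool:
    if pos < lo or pos + span > hi:
        return False
    return all(pos + span + spacing <= s or e + spacing <= pos
               for s, e in taken)


def implant_variants(genome: Plastome, spec: VariantSpec):
    """Implant a truth set into a genome.

    Returns ``(mutated_sequence, truth)`` where ``truth`` is a
    position-sorted list of left-normalized :class:`Variant` such that
    applying it to the original reconstructs the mutated sequence exactly.
    Events are non-overlapping with a minimum spacing; counts are realized
    exactly or an error is raised after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    ref = genome.sequence
    n = len(ref)
    lo, hi = 50, n - 50
    forbidden: list[tuple[int, int]] = []
    if spec.avoid_ir and genome.ir_regions:
        forbidden = [(a - 20, b + 20) for a, b in genome.ir_regions]

    taken: list[tuple[int, int]] = list(forbidden)
    truth: list[Variant] = []
    ilens = sorted(spec.indel_length_distribution)
    iw = np.array([spec.indel_length_distribution[L] for L in ilens], dtype=float)
    iw /= iw.sum()

    runs: list[tuple[int, int, str]] = []  # (start0, length, base) for runs >= 3
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ref[j + 1] == ref[i]:
            j += 1
        if j - i + 1 >= 3:
            runs.append((i, j - i + 1, ref[i]))
        i = j + 1

    def place(kind: str) -> Variant:
        for _ in range(2000):
            if kind in ("ins", "del") and rng.random() < spec.homopolymer_targeting_fraction and runs:
                s0, ln, base = runs[rng.integers(len(runs))]
                if kind == "del":
                    d = 1 if ln <= 3 else int(rng.integers(1, min(3, ln - 1) + 1))
                    v = Variant(s0 + 1, "del", ref[s0 : s0 + d], "-")
                else:
                    d = int(rng.integers(1, 3))
                    v = Variant(s0, "ins", "-", base * d)
            elif kind == "del":
                d = int(rng.choice(ilens, p=iw))
                p = int(rng.integers(lo, hi - d))
                v = Variant(p + 1, "del", ref[p : p + d], "-")
            elif kind == "ins":
                d = int(rng.choice(ilens, p=iw))
                alt = "".join(BASES[rng.integers(4)] for _ in range(d))
                p = int(rng.integers(lo, hi))
                v = Variant(p, "ins", "-", alt)
            elif kind == "SNP":
                p = int(rng.integers(lo, hi))
                r = ref[p]
                alt = [b for b in BASES if b != r][rng.integers(3)]
                v = Variant(p + 1, "SNP", r, alt)
            else:  # MNV
                d = int(rng.integers(2, 5))
                p = int(rng.integers(lo, hi - d))
                r = ref[p : p + d]
                alt = "".join([b for b in BASES if b != c][rng.integers(3)]
                              for c in r)
                v = Variant(p + 1, "MNV", r, alt)
            if v.type in ("ins", "del"):
                v = left_normalize(ref, v)
            span = len(v.ref_allele) if v.ref_allele != "-" else 1
            # reserve the whole repeat tract around an indel so alignment
            # ambiguity cannot bleed into a neighbouring event
            start = v.position - 1
            end = v.position - 1 + span
            if v.type in ("ins", "del"):
                b = (v.alt_allele if v.type == "ins" else v.ref_allele)[-1]
                while end < n and ref[end] == b:
                    end += 1
            if _allowed(start, end - start, taken, spec.min_spacing, lo, hi):
                taken.append((start, end))
                return v
        raise RuntimeError(f"could not place {kind} after bounded retries")

    for kind, count in (("del", spec.n_del), ("ins", spec.n_ins),
                        ("MNV", spec.n_mnv), ("SNP", spec.n_snp)):
        for _ in range(count):
            truth.append(place(kind))

    truth.sort(key=lambda v: (v.position, v.type == "ins"))
    mutated = apply_variants(ref, truth)
    return mutated, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _quals(rng: np.random.Generator, n: int, model: ErrorModel) -> list[int]:
    q = rng.normal(model.mean_q, model.sd_q, size=n)
    return [int(v) for v in np.clip(np.rint(q), 2, 40)]


def _genome_runs(seq: str) -> list[tuple[int, int, str]]:
    """Maximal homopolymer runs as (start0, length, base)."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        runs.append((i, j - i + 1, seq[i]))
        i = j + 1
    return runs


def _hot_sites(rng: np.random.Generator, runs, model: ErrorModel
               ) -> dict[int, str]:
    """Designate systematic error runs (keyed by run start) once per
    simulation."""
    hot: dict[int, str] = {}
    for s, ln, base in runs:
        cls = "AT" if base in AT else "GC"
        pd = model.systematic_del_prob(cls, ln)
        pi = model.systematic_ins_prob(cls, ln)
        u = rng.random()
        if u < pd:
            hot[s] = "del"
        elif u < pd + pi:
            hot[s] = "ins"
    return hot


def _erroneous_fragment(rng: np.random.Generator, seq: str,
                        runs, run_starts: np.ndarray,
                        hot: dict[int, str], start: int, end: int,
                        model: ErrorModel) -> str:
    """Fragment seq[start:end] with platform errors applied, in genome
    orientation."""
    frag = seq[start:end]
    out = list(frag)
    k = rng.binomial(len(frag), model.substitution_rate)
    if k:
        for p in rng.choice(len(frag), size=min(k, len(frag)), replace=False):
            out[p] = [b for b in BASES if b != frag[p]][rng.integers(3)]
    # homopolymer indels: per-run Bernoulli, one event max per run
    events: list[tuple[int, str]] = []
    import bisect
    ridx = bisect.bisect_right(run_starts, start) - 1
    ridx = max(ridx, 0)
    while ridx < len(runs) and runs[ridx][0] < end:
        s, ln, base = runs[ridx]
        ridx += 1
        lo = max(s, start)
        hi = min(s + ln, end)
        if hi <= lo:
            continue
        eff_len = hi - lo
        cls = "AT" if base in AT else "GC"
        sys_ev = hot.get(s) if eff_len == ln else None  # edge-truncated runs skip
        u = rng.random()
        if sys_ev is not None and u < model.systematic_error_rate:
            events.append((lo - start, sys_ev))
            continue
        pd = model.hp_deletion_rate(cls, eff_len)
        pi = model.hp_insertion_rate(cls, eff_len)
        if u < pd:
            events.append((lo - start, "del"))
        elif u < pd + pi:
            events.append((lo - start, "ins"))
    for pos, ev in sorted(events, reverse=True):
        if ev == "del":
            del out[pos]
        else:
            out.insert(pos, frag[pos])
    return "".join(out)


def simulate_reads(genome, model: ErrorModel, coverage: float,
                   seed: int = 0) -> ReadSet:
    """Simulate shotgun reads to the requested fold coverage.

    Paired mode emits proper forward/reverse mates with sampled insert
    sizes; strand is sampled uniformly. Deterministic under seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    seq = genome.sequence if isinstance(genome, Plastome) else genome
    rng = np.random.default_rng(seed)
    L = len(seq)
    rl = model.read_length
    runs = _genome_runs(seq)
    run_starts = np.array([r[0] for r in runs])
    hot = _hot_sites(rng, runs, model)
    reads: list[Read] = []
    if model.paired:
        n_pairs = max(1, round(coverage * L / (2 * rl)))
        for i in range(n_pairs):
            ins = int(np.clip(rng.normal(model.insert_mean, model.insert_sd),
                              rl, L))
            start = int(rng.integers(0, L - ins + 1))
            r1 = _erroneous_fragment(rng, seq, runs, run_starts, hot,
                                     start, min(start + rl, start + ins), model)
            tail = _erroneous_fragment(rng, seq, runs, run_starts, hot,
                                       max(start, start + ins - rl),
                                       start + ins, model)
            r2 = revcomp(tail)
            if rng.random() < 0.5:
                r1, r2 = r2, r1
            pid = f"sim_{model.platform}_{i}"
            for mate, (tag, s) in enumerate((("first", r1), ("second", r2))):
                reads.append(Read(f"{pid}/{mate + 1}", s, _quals(rng, len(s), model),
                                  platform=model.platform, mate=tag, pair_id=pid))
    else:
        n_reads = max(1, round(coverage * L / rl))
        for i in range(n_reads):
            start = int(rng.integers(0, max(L - rl, 0) + 1))
            s = _erroneous_fragment(rng, seq, runs, run_starts, hot,
                                    start, min(start + rl, L), model)
            if rng.random() < 0.5:
                s = revcomp(s)
            reads.append(Read(f"sim_{model.platform}_{i}", s,
                              _quals(rng, len(s), model),
                              platform=model.platform))
    return ReadSet(reads)
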