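"""Read mapping under the platform cost model, pileup, majority consensus."""

import numpy as np
import pytest

from plastidbarcoder import refmap, synth
from plastidbarcoder.refmap import (
    Alignment,
    MappingParams,
    ReferenceIndex,
    build_pileup,
    call_consensus,
    map_read,
    map_reads,
)
from plastidbarcoder.seq_io import Plastome, Read, ReadSet, revcomp
from plastidbarcoder.synth import ErrorModel
from plastidbarcoder.variants import apply_variants, Variant


def nw_glocal_oracle(read, ref, mm=2, ic=3, dc=3):
    """Plain full dynamic program: read global, reference local."""
    m, n = len(read), len(ref)
    D = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        D[i][0] = i * ic
        for j in range(1, n + 1):
            s = 0 if read[i - 1] == ref[j - 1] else mm
            D[i][j] = min(D[i - 1][j - 1] + s, D[i - 1][j] + ic,
                          D[i][j - 1] + dc)
    return min(D[m])


def perfect_read(ref, start, length, rid="r"):
    return Read(rid, ref.sequence[start:start + length], [40] * length)


class TestMapRead:
    def test_exact_read_maps_with_zero_cost(self, genome_5kb):
        r = perfect_read(genome_5kb, 1000, 100)
        res = map_read(r, genome_5kb)
        assert res.status == "mapped"
        a = res.alignment
        assert (a.cost, a.identity, a.ref_start) == (0, 1.0, 1001)

    def test_two_substitutions_accepted_cost_four(self, genome_5kb):
        s = list(genome_5kb.sequence[2000:2030])
        for p in (5, 20):
            s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
        res = map_read(Read("r", "".join(s), [40] * 30), genome_5kb,
                       MappingParams(k=10))
        assert res.status == "mapped"
        assert res.alignment.cost == 4
        assert res.alignment.identity == pytest.approx(28 / 30)

    def test_four_substitutions_below_similarity_unmapped(self, genome_5kb):
        s = list(genome_5kb.sequence[2000:2030])
        for p in (3, 10, 17, 24):
            s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
        res = map_read(Read("r", "".join(s), [40] * 30), genome_5kb,
                       MappingParams(k=5))
        assert res.status == "unmapped"
        assert "similarity" in res.reason

    def test_too_short_read_unmapped_with_reason(self, genome_5kb):
        res = map_read(Read("r", "ACGTACGT", [40] * 8), genome_5kb)
        assert res.status == "unmapped" and "seed" in res.reason

    def test_reverse_strand_read_found(self, genome_5kb):
        r = Read("r", revcomp(genome_5kb.sequence[3000:3080]), [40] * 80)
        res = map_read(r, genome_5kb)
        assert res.status == "mapped" and res.alignment.strand == "-"
        assert res.alignment.ref_start == 3001

    @pytest.mark.parametrize("seed", range(4))
    def test_cost_equals_full_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            n = int(rng.integers(80, 300))
            ref = "".join(rng.choice(list("ACGT"), size=n))
            m = int(rng.integers(20, min(60, n)))
            s0 = int(rng.integers(0, n - m))
            read = list(ref[s0:s0 + m])
            for _e in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, len(read)))
                u = rng.random()
                if u < 0.6:
                    read[p] = str(rng.choice(list("ACGT")))
                elif u < 0.8 and len(read) > 16:
                    del read[p]
                else:
                    read.insert(p, str(rng.choice(list("ACGT"))))
            read = "".join(read)
            res = map_read(Read("r", read, [40] * len(read)),
                           Plastome("ref", ref),
                           MappingParams(length_fraction=0.01,
                                         similarity_fraction=0.01))
            fwd = nw_glocal_oracle(read, ref)
            rev = nw_glocal_oracle(revcomp(read), ref)
            assert res.status in ("mapped", "multimapped")
            got = res.alignment.cost if res.alignment else res.candidates[0].cost
            assert got == min(fwd, rev)


class TestMapReads:
    def test_ir_reads_split_between_copies_deterministically(self, genome_ir):
        (a1, a2), (b1, b2) = genome_ir.ir_regions
        reads = ReadSet([
            Read(f"r{i}", genome_ir.sequence[a1 - 1 + i * 15: a1 - 1 + i * 15 + 100],
                 [40] * 100)
            for i in range(120)
        ])
        params = MappingParams(seed=5)
        alns, rep = map_reads(reads, genome_ir, params)
        assert rep.n_multimapped > 100
        in_a = sum(1 for a in alns if a1 <= a.ref_start <= a2)
        in_b = sum(1 for a in alns if b1 <= a.ref_start <= b2)
        assert in_a + in_b == len(alns)
        assert 0.3 < in_a / len(alns) < 0.7          # ~50/50 split
        alns2, _ = map_reads(reads, genome_ir, params)
        assert [(a.ref_start, a.strand) for a in alns] == \
               [(a.ref_start, a.strand) for a in alns2]

    def test_multimap_discard_policy(self, genome_ir):
        (a1, a2), _ = genome_ir.ir_regions
        reads = ReadSet([Read("r", genome_ir.sequence[a1 + 9: a1 + 109], [40] * 100)])
        alns, rep = map_reads(reads, genome_ir,
                              MappingParams(multimap_policy="discard"))
        assert alns == [] and rep.n_multimapped == 1

    def test_empty_readset(self, genome_5kb):
        alns, rep = map_reads(ReadSet([]), genome_5kb)
        assert alns == [] and rep.width == 0.0

    def test_error_free_coverage_gives_full_width(self):
        g = synth.generate_plastome(synth.GenomeSpec(length=3_000, ir_length=0,
                                                     seed=31))
        reads = synth.simulate_reads(
            g, ErrorModel.illumina(substitution_rate=0.0, paired=False), 50,
            seed=32)
        _alns, rep = map_reads(reads, g)
        assert rep.width == 1.0


class TestPileupAndConsensus:
    def _aln(self, rid, start, query, ops):
        cols = sum(ln for _o, ln in ops)
        matches = sum(ln for o, ln in ops if o == "=")
        consumed_ref = sum(ln for o, ln in ops if o in "=XD")
        return Alignment(read_id=rid, ref_id="ref", ref_start=start,
                         ref_end=start + consumed_ref - 1, strand="+",
                         ops=ops, cost=0, identity=matches / cols, query=query)

    def test_base_tallies(self):
        ref = Plastome("ref", "ACGTACGTAC")
        alns = [self._aln("a", 3, "GTA", [("=", 3)]),
                self._aln("b", 3, "GTA", [("=", 3)]),
                self._aln("c", 3, "CTA", [("X", 1), ("=", 2)])]
        pile = build_pileup(alns, ref)
        p = 2  # 0-based position 3
        assert pile.counts[2, p] == 2      # G x2
        assert pile.counts[1, p] == 1      # C x1
        assert pile.depth[p] == 3

    def test_deletion_tally(self):
        ref = Plastome("ref", "ACGTACGTAC")
        alns = [self._aln("a", 1, "ACTACG", [("=", 2), ("D", 1), ("=", 4)])]
        pile = build_pileup(alns, ref)
        assert pile.counts[4, 2] == 1

    def test_out_of_range_alignment_rejected(self):
        ref = Plastome("ref", "ACGT")
        with pytest.raises(ValueError, match="outside"):
            build_pileup([self._aln("a", 3, "GTAC", [("=", 4)])], ref)

    def test_tallies_equal_brute_force_recount(self):
        g = synth.generate_plastome(synth.GenomeSpec(length=1_000, ir_length=0,
                                                     seed=41))
        reads = synth.simulate_reads(g, ErrorModel.iontorrent(), 10, seed=42)
        alns, _ = map_reads(reads, g)
        pile = build_pileup(alns, g)
        recount = np.zeros_like(pile.counts)
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        for a in alns:
            rpos, qpos = a.ref_start - 1, 0
            for op, ln in a.ops:
                if op in "=X":
                    for t in range(ln):
                        recount[code[a.query[qpos + t]], rpos + t] += 1
                    rpos += ln
                    qpos += ln
                elif op == "D":
                    recount[4, rpos:rpos + ln] += 1
                    rpos += ln
                else:
                    qpos += ln
        assert np.array_equal(pile.counts, recount)
        assert np.array_equal(pile.depth, pile.counts.sum(axis=0))

    def test_zero_error_roundtrip_consensus_equals_reference(self):
        g = synth.generate_plastome(synth.GenomeSpec(length=3_000, ir_length=0,
                                                     seed=51))
        reads = synth.simulate_reads(
            g, ErrorModel.illumina(substitution_rate=0.0, paired=False), 30,
            seed=52)
        alns, _ = map_reads(reads, g)
        res = call_consensus(build_pileup(alns, g), g)
        assert res.consensus == g.sequence

    def test_majority_deletion_removes_position(self):
        ref = Plastome("ref", "ACGTACGTAC")
        alns = ([self._aln(f"d{i}", 1, "ACTACGTAC",
                           [("=", 2), ("D", 1), ("=", 7)]) for i in range(5)]
                + [self._aln("m", 1, "ACGTACGTAC", [("=", 10)])])
        res = call_consensus(build_pileup(alns, ref), ref)
        assert res.consensus == "ACTACGTAC"
        assert len(res.consensus) == len(ref.sequence) - 1

    def test_majority_insertion_requires_plurality_of_spanning_reads(self):
        ref = Plastome("ref", "ACGTACGTAC")
        with_ins = [self._aln(f"i{i}", 1, "ACGTAGACGTAC"[:12],
                              [("=", 5), ("I", 2), ("=", 5)]) for i in range(4)]
        without = [self._aln(f"m{i}", 1, "ACGTACGTAC", [("=", 10)])
                   for i in range(3)]
        res = call_consensus(build_pileup(with_ins + without, ref), ref)
        assert len(res.consensus) == 12
        res2 = call_consensus(build_pileup(with_ins[:2] + without, ref), ref)
        assert res2.consensus == ref.sequence

    def test_systematic_error_length_arithmetic(self):
        # thirty deletion sites (two of them 2 bp) and one insertion site,
        # carried by >=80% of reads: consensus shortens by 31
        g = synth.generate_plastome(synth.GenomeSpec(length=20_000, ir_length=0,
                                                     seed=61))
        rng = np.random.default_rng(62)
        edits = []
        positions = rng.choice(np.arange(200, 19_800, 60), size=31, replace=False)
        for i, p in enumerate(sorted(int(x) for x in positions)):
            if i < 28:
                edits.append(Variant(p, "del", g.sequence[p - 1], "-"))
            elif i < 30:
                edits.append(Variant(p, "del", g.sequence[p - 1:p + 1], "-"))
            else:
                edits.append(Variant(p, "ins", "-", "T"))
        err_genome = apply_variants(g.sequence, edits)
        reads = synth.simulate_reads(
            err_genome, ErrorModel.illumina(substitution_rate=0.0, paired=False),
            25, seed=63)
        alns, _ = map_reads(reads, g)
        res = call_consensus(build_pileup(alns, g), g)
        assert len(res.consensus) == len(g.sequence) - 31
        # length conservation: ref length - majority-deleted positions
        # + total majority-inserted bases
        assert (len(res.consensus) == len(g.sequence)
                - len(res.majority_deletions)
                + sum(len(s) for s in res.majority_insertions.values()))
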