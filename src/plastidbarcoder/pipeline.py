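"""End-to-end orchestration: per-platform trim -> mapping consensus ->
de novo consensus -> variant census, then cross-platform reconciliation
into an amended barcode.

Every stochastic stage derives its seed deterministically from the global
seed and the stage name, so a rerun with the same configuration is
bit-identical. Stage artifacts are plain files (FASTA/TSV/JSON manifest)
when an output directory is configured.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from plastidbarcoder import __version__ as _version
from plastidbarcoder import assembly as _asm
from plastidbarcoder import refmap as _refmap
from plastidbarcoder import reconcile as _rec
from plastidbarcoder import variants as _var
from plastidbarcoder.preprocess import TrimParams, TrimReport, trim_set
from plastidbarcoder.seq_io import Plastome, ReadSet, write_fasta

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    reference: Plastome
    reads: dict[str, ReadSet]                       # platform -> reads
    trim: dict[str, TrimParams] = field(default_factory=dict)
    mapping: _refmap.MappingParams = field(default_factory=_refmap.MappingParams)
    assembly: _asm.AssemblyParams = field(default_factory=_asm.AssemblyParams)
    rules: _rec.ResolutionRules = field(default_factory=_rec.ResolutionRules)
    seed: int = 0
    outdir: Optional[Path] = None

    def trim_params(self, platform: str) -> TrimParams:
        if platform in self.trim:
            return self.trim[platform]
        if platform.startswith("ion"):
            return TrimParams.iontorrent()
        return TrimParams.illumina()


@dataclass
class PlatformResult:
    platform: str
    trim_report: TrimReport
    mapping_report: _refmap.MappingReport
    alignments: list
    consensus: _refmap.ConsensusResult
    contigs: list
    scaffolds: list
    denovo: _asm.JoinResult
    variants: list
    bias: _var.BiasSummary


@dataclass
class CompareResult:
    records: list
    shared: list
    amended: str
    applied_edits: list
    residuals: list


def run_platform(config: PipelineConfig, platform: str) -> PlatformResult:
    """Trim, map, vote a consensus, assemble, scaffold, and call variants
    for one platform's reads."""
    if platform not in config.reads:
        raise KeyError(f"no reads configured for platform {platform!r}")
    ref = config.reference
    trimmed, trim_report = trim_set(config.reads[platform],
                                    config.trim_params(platform))
    logger.info("[%s] trim: %d in, %d kept", platform, trim_report.n_in,
                trim_report.n_kept)
    mp = dataclasses.replace(config.mapping,
                             seed=stage_seed(config.seed, f"map:{platform}"))
    alignments, map_report = _refmap.map_reads(trimmed, ref, mp)
    pile = _refmap.build_pileup(alignments, ref)
    consensus = _refmap.call_consensus(pile, ref)
    logger.info("[%s] mapping: %.3f mapped, width %.3f, mean depth %.1f",
                platform, map_report.mapped_fraction, map_report.width,
                map_report.mean_depth)

    # assembly, with a word-size sweep: when joining fails (long
    # homopolymers reach k-1 and loop the graph), retry at a larger k
    contigs: list = []
    scaffolds: list = []
    denovo = _asm.JoinResult(gap_report=_asm.GapReport(gaps=[(1, len(ref.sequence))]))
    base_k = config.assembly.resolve_k(trimmed.total_bases())
    for k in dict.fromkeys([base_k, 21, 27]):
        aparams = dataclasses.replace(config.assembly, k=k)
        contigs = _asm.assemble(trimmed, aparams,
                                ref=ref if aparams.reference_guided else None)
        contigs = _asm.polish_contigs(contigs, trimmed, mp) if contigs else []
        scaffolds = _asm.align_contigs(contigs, ref) if contigs else []
        denovo = _asm.join_contigs(scaffolds, contigs, ref) if scaffolds else \
            _asm.JoinResult(gap_report=_asm.GapReport(gaps=[(1, len(ref.sequence))]))
        if denovo.joined:
            break
        logger.info("[%s] contigs at k=%d left %d gap(s); retrying", platform,
                    k, len(denovo.gap_report.gaps))

    aln = _var.align_consensus(consensus.consensus, ref)
    variants = [_var.annotate_homopolymer(v, ref)
                for v in _var.extract_variants(aln)]
    bias = _var.summarize_bias(variants)
    result = PlatformResult(
        platform=platform, trim_report=trim_report,
        mapping_report=map_report, alignments=alignments,
        consensus=consensus, contigs=contigs, scaffolds=scaffolds,
        denovo=denovo, variants=variants, bias=bias,
    )
    if config.outdir:
        _write_platform_artifacts(config, result)
    return result


def run_compare(config: PipelineConfig,
                platform_a: str = "illumina",
                platform_b: str = "iontorrent",
                results: Optional[dict[str, PlatformResult]] = None
                ) -> CompareResult:
    """Reconcile two platforms' runs into an amended consensus barcode."""
    results = results or {}
    for p in (platform_a, platform_b):
        if p not in results:
            results[p] = run_platform(config, p)
    ra, rb = results[platform_a], results[platform_b]
    records = _rec.diff_variant_sets(ra.variants, rb.variants)
    shared_loci = {v.locus: v for v in ra.variants}
    shared = [v for v in rb.variants
              if v.locus in shared_loci
              and shared_loci[v.locus].alt_allele == v.alt_allele
              and shared_loci[v.locus].ref_allele == v.ref_allele]
    contigs_by_source = {
        platform_a: (ra.contigs, ra.scaffolds),
        platform_b: (rb.contigs, rb.scaffolds),
    }
    alns_by_platform = {platform_a: ra.alignments, platform_b: rb.alignments}
    for rec in records:
        ev = _rec.gather_evidence(rec, contigs_by_source, config.reference,
                                  alignments_by_platform=alns_by_platform)
        _rec.resolve(rec, ev, config.rules)
    amended, applied = _rec.amend_consensus(config.reference, records, shared)
    remap_reads = config.reads.get(platform_a) or ReadSet([])
    residuals = _rec.validate_by_remap(
        amended, remap_reads,
        dataclasses.replace(config.mapping,
                            seed=stage_seed(config.seed, "remap")))
    result = CompareResult(records=records, shared=shared, amended=amended,
                           applied_edits=applied, residuals=residuals)
    if config.outdir:
        _write_compare_artifacts(config, result)
    return result


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

def _manifest(config: PipelineConfig, extra: dict) -> dict:
    return {
        "version": _version,
        "seed": config.seed,
        "reference": {"id": config.reference.id,
                      "length": len(config.reference)},
        "mapping": dataclasses.asdict(config.mapping),
        "assembly": dataclasses.asdict(config.assembly),
        **extra,
    }


def _write_platform_artifacts(config: PipelineConfig, r: PlatformResult) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / f"{r.platform}.mapping_consensus.fasta",
                (f"{r.platform}_mapping_consensus", r.consensus.consensus))
    if r.contigs:
        write_fasta(out / f"{r.platform}.contigs.fasta",
                    [(c.id, c.sequence) for c in r.contigs])
    if r.denovo.joined:
        write_fasta(out / f"{r.platform}.denovo_consensus.fasta",
                    (f"{r.platform}_denovo_consensus", r.denovo.consensus))
    else:
        with open(out / f"{r.platform}.gaps.tsv", "w", newline="\n") as fh:
            fh.write("gap_start\tgap_end\n")
            for s, e in r.denovo.gap_report.gaps:
                fh.write(f"{s}\t{e}\n")
    with open(out / f"{r.platform}.variants.tsv", "w", newline="\n") as fh:
        fh.write("position\ttype\tref_allele\talt_allele\trun_length\tbase_class\n")
        for v in r.variants:
            ctx = v.context
            fh.write(f"{v.anchor_label}\t{v.type}\t{v.ref_allele}\t{v.alt_allele}\t"
                     f"{ctx.run_length if ctx else ''}\t"
                     f"{ctx.base_class if ctx else ''}\n")
    stats = {
        "trim": dataclasses.asdict(r.trim_report),
        "mapping": dataclasses.asdict(r.mapping_report),
        "n_variants": len(r.variants),
        "variant_types": {
            t: sum(1 for v in r.variants if v.type == t)
            for t in ("SNP", "MNV", "ins", "del")},
    }
    (out / f"{r.platform}.manifest.json").write_text(
        json.dumps(_manifest(config, {"platform": r.platform, "stats": stats}),
                   indent=2) + "\n")


def _write_compare_artifacts(config: PipelineConfig, r: CompareResult) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "amended_consensus.fasta", ("amended_consensus", r.amended))
    with open(out / "reconciliation.tsv", "w", newline="\n") as fh:
        fh.write("no\tposition\tref_allele\tallele_a\tallele_b\t"
                 "most_probable\tresolution\trule\n")
        for i, rec in enumerate(r.records, 1):
            fh.write(f"{i}\t{rec.anchor_label}\t{rec.ref_allele}\t"
                     f"{rec.allele_of('a')}\t{rec.allele_of('b')}\t"
                     f"{rec.resolved_allele}\t{rec.resolution}\t{rec.rule}\n")
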