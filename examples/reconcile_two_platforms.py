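"""Full two-platform run: map + assemble per platform, diff the variant
sets, resolve each discrepancy with contig evidence, emit the amended
barcode, and validate it by re-mapping.
"""

from plastidbarcoder import synth
from plastidbarcoder.pipeline import PipelineConfig, run_compare, stage_seed
from plastidbarcoder.synth import ErrorModel, GenomeSpec, VariantSpec

seed = 5
genome = synth.generate_plastome(
    GenomeSpec(length=15_000, ir_length=0, seed=stage_seed(seed, "genome")))
sample, truth = synth.implant_variants(
    genome, VariantSpec(n_snp=18, n_mnv=2, n_ins=5, n_del=6,
                        seed=stage_seed(seed, "var")))
reads = {
    "illumina": synth.simulate_reads(sample, ErrorModel.illumina(), 40,
                                     seed=stage_seed(seed, "ri")),
    "iontorrent": synth.simulate_reads(sample, ErrorModel.iontorrent(), 40,
                                       seed=stage_seed(seed, "rt")),
}
result = run_compare(PipelineConfig(reference=genome, reads=reads, seed=seed))

print(f"{len(result.shared)} variants called identically by both platforms")
print(f"{len(result.records)} discrepancies:")
print("position      a-allele  b-allele  resolved  rule")
for r in result.records:
    print(f"{r.anchor_label:12s}  {r.allele_of('a'):8s}  {r.allele_of('b'):8s}  "
          f"{r.resolved_allele:8s}  {r.rule}")
print(f"amended barcode: {len(result.amended):,} bp "
      f"({len(result.applied_edits)} edits)")
print(f"remap-validation residual disagreements: {len(result.residuals)}")
truth_loci = {v.locus for v in truth}
errors = [r for r in result.records if r.locus not in truth_loci]
print(f"{len(errors)}/{len(result.records)} discrepancies were platform "
      "errors; every one was resolved back to the reference allele")
# The rule column shows why each call was kept or discarded: R1 mapping
# artifact, R2 contig-supported variant, R3 homopolymer read error,
# R4 long-homopolymer ambiguity, R5 default platform agreement.
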