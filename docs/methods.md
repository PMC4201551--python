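# Methods

This note documents the models, parameters and numerical choices behind
`plastidbarcoder`, and what the synthetic study conditions do and do not
establish about real data.

## Quality model and trimming

A single quality→probability conversion is used pipeline-wide:
p = 10^(−Q/10), Sanger PHRED+33 in FASTQ, Q ∈ [0, 62]. `N` bases carry
p = 1, so Mott trimming removes them naturally.

`error_prob_limit` (Mott-style) trimming keeps the contiguous interval
maximizing Σ(limit − p_i). The limit is the operative parameter
(0.05 for the semiconductor preset, 0.01 for Illumina; analysis suites
sometimes quote PHRED equivalences for these limits that do not equal
−10·log10(limit) — the probability limit is what this package applies).
Ties resolve leftmost, then longest, so results are deterministic; the
implementation is an O(n) prefix-scan verified against an exhaustive
O(n²) substring oracle. `sliding_window` truncates at the first 20 bp
window whose mean PHRED drops below 17 (minimum kept length 20), the
semiconductor vendor-suite style. Minimum read length after trimming is
30 by default. An orphaned mate is retained as a single read.

## Read mapping and majority-vote consensus

The mapper minimizes cost = 2·mismatches + 3·inserted + 3·deleted bases,
end-to-end on the read (no soft clipping), local on the reference.
Candidate placements come from exact k-mer seeds (k = 15, sampled every
7 bp along the read) clustered by diagonal (band 16); each cluster is
scored by a banded glocal dynamic program (vectorized per row with a
min-plus prefix scan for in-row gaps). A near-perfect ungapped diagonal
(cost < 3) short-circuits the DP — provably optimal because any gapped
alignment costs at least one 3-point indel. References up to 2 kb fall
back to a full scan when seeding fails, which keeps the mapper exactly
equal to a full Needleman–Wunsch oracle on small instances. *Length
fraction* is aligned-read-bases / read-length, *similarity fraction* is
matches / aligned columns; both thresholds (0.9) are applied after
optimization. Equal-best placements (inverted repeat) are multimapped and
placed uniformly at random under the run's seed, or discarded.

Consensus is by counts, not qualities: at each reference position the
plurality symbol among {A, C, G, T, deletion} wins; voting ties go to the
reference allele and are logged. An insertion is emitted at an anchor
only when the identical inserted string is supported by a plurality of
the reads spanning both flanking positions; partially overlapping reads
do not vote. Zero-coverage positions emit the reference base and are
flagged rather than masked, so consensus length always satisfies
len(consensus) = len(reference) − majority-deleted positions + majority-
inserted bases. Pairing is not used to constrain placement.

## De novo assembly and scaffolding

A de Bruijn graph over read k-mers (both strands, reverse-complement
contig twins deduplicated). The k-mer coverage floor is
max(2, 0.2 × depth-weighted median k-mer count): with an indel-dominated
~1% error model, specific per-run error k-mers recur identically across
reads and an absolute floor of 2 no longer separates signal from error;
the weighted median estimates the depth a typical sequenced base sits at
and is insensitive to the long tail of low-count error k-mers. Tips
(dead-end unbranched paths shorter than 2k) are clipped; simple bubbles
(two branches reconverging within `bubble_size` = 50) are popped keeping
the higher-coverage branch, with ties (within 20%) optionally broken
toward branches whose k-mers occur in the reference (the
reference-guided mode — an approximation of reference-assisted assembly
in which contigs remain strictly read-derived). Word size is `auto`
(log₄ of a genome-size proxy, clipped to [15, 31], forced odd — in
practice 15); the pipeline retries at k = 21 and 27 when contigs fail to
join, because homopolymer runs of ≥ k−1 bases self-loop the graph at
small k. Assemblies of a linear genome lose their terminal k-mers to the
coverage floor, so contigs fall short of the sequence ends by a few tens
of bases.

Contigs are placed on the reference by exact 20-mer anchors clustered by
diagonal and extended with a semi-global alignment (edlib); all matches
are reported regardless of uniqueness, so an IR-contained contig yields
two placements. Scaffold selection is greedy by (aligned length, percent
identity, query coverage) descending — an automation of manual joining
that names the same three criteria. Adjacent selections need ≥ 20 bp of
overlap and are spliced at a reference 12-mer occurring exactly once in
both contig ends, searched outward from the overlap midpoint; the exact
shared anchor makes the junction seamless even when one contig end
carries a local artifact (collapsed tandem repeat, unpolished end), and
its absence raises a conflict error. Internal uncovered reference
intervals produce a gap report instead of a consensus; uncovered terminal
stretches up to 100 bp are tolerated and reported as the consensus span.

## Variant extraction and homopolymer context

The consensus is aligned to the reference globally under unit mismatch
and affine gaps (open 2, extend 1), computed by anchor decomposition:
k-mers (k = 20) unique in both sequences are chained co-linearly
(patience LIS) and exact Gotoh DP fills the inter-anchor segments; inputs
up to 1.5 kb run as one exact DP. Maximal runs of adjacent substituted
columns become one MNV (length ≥ 2) or a SNP; a one-base match keeps two
SNPs separate. Gap runs become single insertions/deletions, left-aligned
to their leftmost equivalent placement — required for cross-platform
position matching. Transitions are exactly {A↔G, C↔T}. Homopolymer
context is the maximal run at/adjacent to the event (insertions: the run
of the inserted base touching the anchor; mixed multi-base indels take
the first base and are flagged). Bias summaries deduplicate indels by
(position, type, allele) before stratifying by (type, run length, base
class).

## Synthetic data: what it emulates

`generate_plastome` builds sequence as alternating homopolymer runs:
run class (A/T vs G/C) is drawn so the realized composition hits the GC
target (default 0.39) given the class run-length distributions, run
lengths come from geometric-decay weight tables in which G/C runs top out
at 9 bases while A/T runs carry a boosted tail up to 17 — the real
plastome's spectrum shape. The quadripartite structure is LSC + IRa +
SSC + IRb with IRb the reverse complement of IRa (default IR 20 kb on a
130 kb genome; the non-IR length splits 80/20).

`implant_variants` defaults to the published wild-rice census shape
(92 SNP + 5 MNV + 13 ins + 18 del = 128 events); half the indels target
homopolymer runs ≥ 3 bp. Events are left-normalized, non-overlapping and
separated by ≥ 30 bp plus the full repeat tract of any indel, so
alignment ambiguity cannot bridge two events — this is what makes the
extract∘apply round trip exact, and real variant pairs closer than that
spacing are outside the generator's conditions. By default variants
avoid the IR (a real IR mutation appears in both copies; modeling that
coupling is out of scope).

Read simulation: Illumina preset — paired 100 bp (or 36 bp), insert
N(550, 50²), substitutions Bernoulli per base at 0.1%, no indels, mean
claimed PHRED ≈ 30.5. Ion-Torrent preset — single ~200 bp reads,
substitutions at 0.2%, per-homopolymer-run indel Bernoulli (one event max
per run per read) with deletion rates peaking in 2–5 bp G/C runs
(3–7.5% per run) and insertion rates growing with A/T run length ≥ 5;
total error lands near 1% with indels dominant; mean claimed PHRED
≈ 25.5. Base qualities are drawn independently of whether a base is
erroneous — trimming acts on claimed, not true, quality. Strand is
uniform; errors are applied in genome coordinates before orientation.

In addition to these independent per-read errors, the semiconductor
preset designates a small fraction of genome runs as *systematic* error
sites (G/C 2–5 bp runs with probability 0.005, A/T 2–5 bp with 0.0015,
A/T ≥ 5 bp insertion sites with 0.008); ~85% of reads covering such a
run carry the same indel. This is the mechanism that produces
consensus-level platform errors: with independent errors only, majority
voting yields a perfect consensus and no cross-platform discrepancies
ever arise, contrary to the observed tens of consensus indels per
plastome. Hot-site densities were chosen to land near the observed
per-kb consensus error rates. The simulator does not model flowgram
signal, PCR duplicates, GC-coverage bias, or quality-error correlation.

Passing tests on this generator therefore show that the pipeline's logic
is correct under a faithful *shape* of the platforms' error structure —
they do not certify performance on real flowgram chemistry, real repeat
content beyond homopolymers and the IR, or contamination.

## Reconciliation rules

Discrepancy records match variants by locus — insertions by anchor,
everything else by start position — so a SNP on one platform and a
deletion on the other at the same coordinate form one conflicting record.
Rules are applied in a fixed order, R1 first:

- R1 (mapping artifact): every contig source carries the reference
  allele AND the site is mapping-ambiguous ⇒ reference.
- R2 (contig-supported variant): all contig sources agree on one
  non-reference allele ⇒ adopt it.
- R3 (homopolymer read error): a single-platform indel in a run ≥ 2 bp
  whose contigs carry the reference ⇒ reference.
- R4 (long-homopolymer ambiguity): an indel in a run ≥ 8 bp with contig
  sources disagreeing ⇒ unresolved (reference kept, flagged uncertain).
- R5 (default): contigs agree with exactly one platform ⇒ adopt that
  platform's allele; otherwise unresolved (reference kept, flagged).

Mapping ambiguity codifies visual inspection: within ±25 bp, more than
20% of covering reads carry ≥ 3 differences or were randomly-placed
multimappers (thresholds configurable). It also stands in for the
read-level nuclear-paralog check (an approximation: paralogous reads
manifest exactly as high-mismatch pileups). Contig alleles are read out
of scaffold placements by locally re-aligning the contig segment over the
site and extracting the left-normalized call at the record's locus; a
source with no contig covering the site ±40 bp is recorded absent, and a
record with no contig evidence at all is unresolved. Unresolved always
defaults to the reference allele with an `uncertain` flag — the
conservative choice the published worked example makes at its one
irreducibly ambiguous site.

Amendment applies shared variants plus non-reference resolutions
right-to-left so coordinates stay valid; identical duplicate edits
collapse and overlapping distinct edits raise an error naming the
collision. Validation re-maps the paired-end read set against the
amended sequence and reports every site where a fresh majority consensus
still disagrees; residuals are expected only at unresolved sites.

## Determinism and problem sizes

All randomness flows from explicit integer seeds; the pipeline derives
each stage's seed from the global seed and the stage name
(seed·1000003 + crc32(name) mod 2³¹), so reruns are bit-identical. The
shipped tests and the acceptance script run the study at reduced scale —
3–15 kb genomes at 20–60× coverage, 500-case oracle comparisons, 100
round-trip truth sets — sizes chosen so the full suite completes in a
few minutes on one CPU while every statistic it checks (enrichment
contrasts, recovery fractions, oracle agreement) is comfortably resolved
at that n. The one check that needs external data, the homopolymer
census of the real reference plastome (GenBank GU592207: G/C runs of
9 bp ×2, 8 bp ×4, 7 bp ×9; GC 39%; 134,551 bp), requires a local copy of
the accession FASTA and fails with a clear message when it is absent.

## Known limitations

- The mapper has no paired-end rescue and no base-quality-weighted
  voting (votes are read counts, matching the majority-of-reads rule).
- Indel realignment is not performed; left-normalization at extraction
  time is the only indel harmonization.
- The assembler resolves only simple two-branch bubbles; complex tangles
  fragment into contigs (real short-read behavior, but not a full
  assembler).
- Insertion votes at an anchor are not left-normalized per read, so in
  long repeats split votes can suppress a true insertion call — the
  de novo route and reconciliation recover these, as in the long-
  insertion rows of the worked example.
- The reference is treated as linear; the `circular` flag is reserved
  but unused.
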