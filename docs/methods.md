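# Methods

This note documents the models and procedures implemented in `splicebench`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Annotation model and counting bins

Transcript structure is parsed from GTF (1-based closed) into 0-based
half-open intervals. Each gene is flattened by cutting the genome at every
exon boundary of every transcript of the gene: within each elementary
interval the set of covering transcripts is constant, so membership is
exact, and adjacent intervals with identical membership are merged. The
result is a set of disjoint, sorted *counting bins* that exactly partition
the union of exon bases. A bin with a single member transcript is
*transcript-specific* (a discriminating exon).

Design choices: discriminating exons are defined on bins rather than whole
annotated exons, because whole-exon specificity is undefined when exons
partially overlap; strand is ignored for binning; transcripts of a gene
annotated on both strands are kept under one gene id as annotated. GTF
parsing is done by a small line-oriented reader so that malformed records
can be reported with their line number and exon records lacking
`transcript_id`/`gene_id` can be rejected outright.

## Candidate selection

Given background counts per bin (features × samples, groups C and T), the
spike-candidate chain keeps, in order:

1. genes with ≥ `min_isoforms` (default 3) splice variants;
2. genes with ≥ 1 transcript owning ≥ 1 transcript-specific bin;
3. transcripts whose transcript-specific bins sum to ≥
   `min_discriminating_total` (default 10) counts over **all** samples of
   both groups; the boundary is inclusive (exactly 10 survives), and the
   filter drops transcripts, not genes — a gene survives while any of its
   transcripts does.

Survivor counts per stage are recorded for audit. The final manual-curation
step a human would apply is replaced by a seeded uniform sample without
replacement over candidate genes, one transcript per gene, so selection is
reproducible and unbiased.

## Spike read simulation

Reads are 2×`read_length` (default 51 nt) mate pairs in FR orientation
from `fragment_length` (default 150 nt) fragments of the spliced
transcript sequence; mate 2 is the reverse complement of the fragment's 3′
end. The 150 nt default reflects the typical insert size of short-read
RNA-seq libraries. Base qualities are constant (`base_quality`, default
Phred 40, written as `I` in Phred+33).

Fragment starts are placed deterministically: with `S = spliced_length −
fragment_length + 1` admissible starts, full passes use every start once
and a final partial pass of `k` fragments uses starts `floor(j·S/k)`.
Consequences, all asserted against a per-base pileup oracle:

- start usage is exactly balanced when the fragment count is a multiple of
  `S` and never differs by more than one otherwise;
- per-base mate coverage is constant on the central plateau
  `[fragment_length − 1, spliced_length − fragment_length]`;
- every internal exon–exon junction is spanned by at least one mate
  whenever the fragment count reaches `S`.

True per-base uniformity over the *entire* transcript is impossible for
bounded-length reads — positions within one read length of the termini are
necessarily covered by fewer mates — so uniformity is stated and tested on
start balance, the plateau, and junctions. Deterministic tiling was chosen
over uniform random starts because random placement only approximates
junction coverage, while the benchmark needs it guaranteed.

## Replicate count noise

The number of read pairs injected per replicate is sampled in two steps:
a population of `population_size` (default 10⁵) draws from
Normal(μ, μ/10) is rounded half-up to integers and clipped at zero, and
the per-replicate counts are drawn from that population without
replacement. The σ = μ/10 rule emulates the tight technical-replicate
variability of spike-ins; rounding/clipping makes counts valid
non-negative integers (negligible at the default means, since μ = 100
puts zero at 10σ). The population's mean/sd ratio is therefore 10 up to
sampling error (standard error of the sd at n = 10⁵ is ≈ 0.22%).

A transcript may carry one plan entry per group with different means,
encoding an expected log₂ fold change of log₂(μ_T/μ_C); this is how
benchmarks with known finite fold changes are built. A transcript spiked
into only one group is flagged `exclusive_presence` in the truth table and
its fold change is left undefined rather than infinite. Duplicate
(transcript, group) entries are rejected.

## Extraction mode

Instead of synthetic reads, pairs can be harvested from a
coordinate-sorted, indexed BAM: a pair qualifies when at least one mate
overlaps at least one exon of the target transcript, pairs are kept intact
(both mates or neither, restored to as-sequenced orientation), unpaired or
mate-missing alignments are skipped with a logged count, and an
over-supply is reduced by a seeded subsample. Original base qualities are
preserved. Note the inherent ambiguity of extraction: a read on a shared
exon cannot be attributed to one isoform, which is why the synthetic mode
exists.

## Injection and the truth table

Per sample, the output FASTQ is the background records followed by the
spike records, mate files kept in matching order, so record counts add
exactly — an invariant tested byte-for-byte. The truth table records
per-transcript per-replicate injected counts (taken from the plan's
realised draws, or tallied from structured read ids), the target group(s)
and the expected log₂ fold change. Read ids embed the origin transcript
(`spike|<transcript>|<serial>`) for debuggability; `--anonymize-reads`
strips the truth from ids for blind benchmarking.

## Background fixture generator

The generator emulates a null two-group experiment: a random genome with
multi-isoform genes, negative-binomial counts per bin with identical group
means, and background reads drawn per transcript proportional to the mean
count of its bins, with seeded random fragment starts (random rather than
tiled, to look alignment-realistic). Isoforms are independent exon subsets
(keep probability 0.7, ≥ 2 exons); with probability `cassette_prob`
(default 0.8) a gene gets a planted cassette exon private to one isoform,
so a realistic fraction of genes carries a discriminating exon. Defaults —
20 genes, 1–5 isoforms, 100–250 nt exons, 5+5 replicates, NB mean ≈ 30
with dispersion 0.1 — keep every stage exercised in seconds.

What the generator does **not** model: sequencing error, PCR duplicates,
GC or positional bias, adapter read-through, rRNA contamination, or
expression correlation structure beyond shared counting bins. Passing
tests therefore demonstrate the correctness of the benchmark machinery and
the behaviour of callers under idealised noise, not caller performance on
real libraries.

Because isoforms of a gene share counting bins, their derived
per-transcript counts are correlated; with few replicates a gene whose
bins drift by chance can push several isoforms over a significance
threshold together. This is a genuine property of exon-shared counting
(real callers face it too) and is visible as occasional false-positive
clusters in the worked example.

## Detection filter and overlap matrix

A transcript is detected when FPKM > 0.1 **and** average coverage > 0,
both strict, with duplicate transcript rows rejected. The overlap matrix
between detected sets is row-normalised: entry (i, j) =
100·|Sᵢ∩Sⱼ|/|Sᵢ|, so it is deliberately asymmetric — a small library
preparation's detected set can lie almost entirely inside a large one
while covering under half of it — and rows for empty sets are reported as
not available. Row (rather than column) normalisation is a documented
choice; the identity |Sᵢ|·Mᵢⱼ = |Sⱼ|·Mⱼᵢ ties the two directions together.

## Calling rules and scoring

- Transcript level: call iff q ≤ α (default 0.05, inclusive).
- Exon level: raw p-values are BH-adjusted jointly across all bins (not
  per gene — a documented choice; pre-adjusted input is accepted via a
  flag); a transcript is called iff ≥ 1 of its *transcript-specific* bins
  has adjusted p ≤ α. Significant bins shared by ≥ 2 transcripts never
  trigger a call, because they cannot implicate a single variant.
- Scoring: TP = called ∩ truth, FP = called \ truth, detection % =
  100·TP/|truth|, realized FDR = FP/max(TP+FP, 1).
- MA statistics per feature: log₂((mean_T + ε)/(mean_C + ε)) against
  log₁₀(mean over all samples + ε) with pseudocount ε = 0.5 (configurable)
  to keep zero counts finite.

BH adjustment is delegated to `statsmodels`' step-up implementation and is
cross-checked in the tests against an independent brute-force definition.
A small built-in reference caller (Welch's t-test on log₂(count+1), BH
adjusted) powers end-to-end smoke runs; benchmark users are expected to
feed their own caller's table.

## Orchestration, determinism, problem sizes

The CLI chains the stages with a YAML config; unknown keys are schema
errors, and a missing upstream artifact names the stage to run first.
Seeds are mandatory (no wall-clock default); every stochastic component
derives its generator from the run seed plus a fixed offset or entry
index, so repeated runs are byte-identical and stage manifests record
matching output checksums.

Test and demonstration problem sizes were chosen so a complete run takes
seconds on one CPU: toy genomes of 12–40 genes, 3–5 replicates per group,
spike means of 50–400 read pairs per replicate, ~10⁵ simulated read pairs
at most. The end-to-end recovery check plants log₂ fold changes in
{−2, −1, 1, 2} (five transcripts each) at base mean 100 on a 40-gene
fixture and requires every |lfc| = 2 spike to be detected with realized
FDR ≤ 0.1 at α = 0.05.

## Known limitations

- FPKM/coverage quantification from alignments is out of scope; the
  package consumes quantifier output as generic tables (the CLI's
  `compare` stage derives proxy FPKM/coverage from labelled read counts
  for smoke purposes only).
- Extraction mode cannot disambiguate reads on shared exons.
- The built-in reference caller is a smoke-test device, not a recommended
  analysis method; its FDR behaviour under correlated isoform counts is
  visibly imperfect by design.
- No GFF3 input in this version; novel (unannotated) splice variants are
  out of scope throughout.
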