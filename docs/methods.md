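# Methods

This note documents the statistical models, conventions and design choices
behind `brinepop`, in the order data flows through the package.

## Coordinates and formats

All internal coordinates are 0-based, half-open. SAM (1-based POS) and GFF3
(1-based closed) are converted at the file boundary and nowhere else.
Reverse-strand reads are stored reference-forward; every pileup statistic is
strand-agnostic. Alignments are read and written through pysam using a
minimal SAM dialect (`@HD`, `@SQ`, FLAG, POS, CIGAR, NM); when NM is absent
it is reconstructed from MD + CIGAR, and a record with neither is rejected.
Reference N bases are excluded from allele counting (undefined reference
allele). Circular contigs are carried as a flag only: the generator emits
linearized alignments and all analyses treat contigs as linear, since no
wrap-around convention exists for the coverage and diversity rules
implemented here.

## Synthetic communities

The generator exists so that every inference stage can be scored against
exact truth. It emulates:

- **Genomes** — i.i.d. uniform base composition, with non-overlapping
  coding genes (`ATG` + sense codons + stop, length divisible by 3, either
  strand) placed at ~1 gene/kb with bodies of 300–900 bp, giving ~60%
  coding density. Genes, and all injected mutations, stay at least one read
  length away from contig ends, because the uniform-start read layout
  leaves a depth ramp there that would confound recovery scores for reasons
  unrelated to the estimators under test.
- **Strain pools** — a site mutated in a strain subset with pooled
  frequency *f* contributes expected heterozygosity 2*f*(1−*f*). Sites are
  drawn until the accumulated expectation reaches `target_pi × L`, so the
  genome-wide expected π equals the target; the realized truth π is then
  computed exactly from the strain sequences. Coding mutations are chosen
  synonymous or nonsynonymous with probability `frac_nonsyn`, classified
  against the reference codon at injection time (translation table 11);
  substitutions creating stops, and sites in start/stop codons, are
  redrawn. Multiple mutations may share a codon; each is classified
  independently against the reference codon, matching the downstream
  pN/pS convention.
- **HVR analogues** — an interval replaced by unrelated random sequence in
  strains comprising a requested fraction of the pool. Reads from the
  replaced haplotypes mismatch the reference at ~75% of positions, fail the
  identity filter, and coverage collapses — the mechanism by which real
  hypervariable regions appear as coverage islands.
- **Reads** — uniform start positions, substitution-only errors at a fixed
  per-base rate, read count `round(depth × L / read_len)`. The generator
  emits the truth SAM itself (exact origin placement, NM = injected errors
  + strain-versus-reference mismatches), so the pipeline is testable with
  no external mapper; a real mapper's SAM is accepted interchangeably.
- **Transcriptomes** — reads drawn only from gene intervals of a declared
  active genome set, so activity calling has an exact truth.

What the generator does **not** emulate: indels and structural variants,
GC/positional coverage bias, quality-score structure, chimeric reads,
mapping ambiguity between related references, and linkage between strain
haplotypes beyond co-assignment of mutations to strains. Passing tests
therefore demonstrate correctness of the inference rules under their own
assumptions (substitution-dominated divergence, roughly even coverage),
not robustness to mapper artefacts or indel-rich data.

## Viral classification and vOTUs

Classification is the four-criterion OR rule over detector fields; absent
fields simply fail their criteria, and all satisfied criteria are reported.

`pairwise_ani` anchors exact 15-mers shared between two sequences, groups
anchors by diagonal, spans each diagonal's anchors into one ungapped block,
drops blocks under 100 bp, trims overlaps so no position is double-counted,
and returns the length-weighted percent identity over retained blocks plus
the percent of the shorter sequence covered. This is exact for
substitution-dominated divergence (an indel shifts the diagonal and starts
a new block) and is cross-checked against an exhaustive local-DP oracle
(Biopython PairwiseAligner, match 1 / mismatch −1 / gap −2) that recomputes
both quantities from the optimal alignment path.

Clustering is greedy and representative-anchored: contigs sorted by length
descending (ties by id), each joining the first cluster whose
representative meets ANI ≥ 95 and aligned fraction ≥ 80, else founding a
new cluster — so the longest member is always the seed, the result is a
partition, and the procedure is order-deterministic. "80% of their
lengths" is interpreted as 80% of the **shorter** sequence, the convention
of the clustering lineage this rule comes from; both thresholds are
parameters. Contaminant screening applies the same rule against an
exclusion list.

## Coverage, abundance, HVRs

Read identity is edit-distance style, `1 − NM / alignment columns`
(insertions and deletions count as columns); the aligned read fraction is
query-consumed columns over read length (soft clips excluded). Defaults are
95% / 90% for viromic abundance and 90% / 90% for transcript recruitment,
each separately configurable. Depth counts every reference-consumed
position once per retained read (deletions cover). Mean depth is taken over
all positions, zeros included, and abundance is mean depth × 10⁹ / library
bases. Presence of a vOTU in a sample defaults to breadth ≥ 0.70 at depth
≥ 1 — a declared convention, since presence rules are rarely printed;
it is exposed as a parameter.

HVR detection: a contig is eligible when median depth (all positions,
zeros included) ≥ 5×; a position is low when depth ≤ 0.20 × median
(inclusive); islands are maximal runs of low positions ≥ 500 bp. Runs are
strict by default; `max_gap` can bridge short interruptions. Because the
rule is a ratio against the contig's own median, uniform depth rescaling
leaves calls unchanged. Median (not mean) anchors the eligibility rule so
a single deep hotspot cannot qualify a mostly uncovered contig.

## Microdiversity

A site is **eligible** at depth ≥ `min_cov` (10). An allele is a variant
when it differs from the site consensus (most frequent allele, ties toward
the reference base) with count ≥ `min_count` (4) and frequency ≥
`min_freq` (0.01). These thresholds are this package's declared defaults,
chosen so that at 50× depth a 0.1% substitution error rate yields
essentially no false alleles (the chance of four identical errors at one
site is negligible) while alleles at ≥ 10% frequency are kept with near
certainty.

π at a site is the unbiased estimator `Σ_{a≠b} c_a c_b / (n(n−1))`;
region π is the mean of site π over eligible sites. Counts are first
**denoised** — alleles failing the variant thresholds are zeroed (consensus
kept) — because the raw estimator's expectation includes ~2e per site of
error heterozygosity, which at e = 0.001 would swamp a true π of 0.001.
With denoising the estimator tracks the truth-strain oracle within ~3%
across π ∈ [0.001, 0.02] at 50×.

pN/pS is Nei–Gojobori style. Site totals: for each codon whose three
positions are all eligible, each of the nine single-base mutants is
classified by the genetic code; the synonymous site count is the
per-position synonymous fraction summed over positions, nonsynonymous is
its complement (stop-creating mutants count nonsynonymous); totals sum
over such codons only, keeping numerator and denominator on the same site
set. Observed counts: every segregating allele differing from the
*reference* base (reported alts plus the consensus when it is non-reference)
counts once, classified by substituting it into the reference codon on the
gene's strand. A gene with variants but `S_obs = 0` gets the pseudocount
ratio `(N_obs+1)/(S_obs+1)` on observed counts only (sites unchanged),
flagged `pseudocount` — avoiding infinite ratios while preserving the
ratio > 1 decision for genuinely nonsynonymous-dominated genes. A gene with
no variants is classed `no-variation`, not assigned a ratio. Genes whose
reference frame breaks (length not divisible by 3, internal stop) are
rejected. Group contrasts use two-sided Wilcoxon rank-sum tests on
per-contig or per-gene statistics.

## Macrodiversity and activity

Shannon uses the natural log (base is a parameter). Venn partitions report
each region's vOTU count and per-sample summed relative abundance.
Rank-abundance series order by one sample's abundances (ties by id) and
append the other sample's exclusive vOTUs by their own abundance.
Rarefaction subsamples reads without replacement under a fixed seed,
recomputes detection (breadth ≥ 0.70) at each depth, fits a least-squares
line through the last four points, and reports the slope as expected new
vOTUs per additional 10⁶ reads. Activity follows the 90/90/50 triple:
identity / read-fraction filters then breadth ≥ 0.5.

## Validation design and problem sizes

The validation experiments (`brinepop.validation`, driven by the analysis
scripts, the acceptance tests and `scripts/acceptance.py`) use: five 50 kb
genomes at 50× for π recovery (2–4 strains, π targets 0.001/0.005/0.02,
error 0.001); one 40 kb gene-dense genome, two arms at matched mutation
load (coding-only π 0.004) for pN/pS directionality; three 40 kb genomes at
60× error-free with 50/50 strain pairs for SNP exactness; twenty 30 kb
genomes at 25× with one 1–2 kb island each for HVR recovery; and fifty
contigs of 1.5–5 kb for the clustering oracle. These sizes give each
statistic enough events to be stable (hundreds of SNPs, tens of genes and
islands) while keeping any single experiment under about two minutes on
one CPU.

Two validation choices deserve note. The HVR islands are replaced in 99%
of strain mass: near 80% replacement the island depth sits exactly at the
20%-of-median boundary, and with strict (gap-free) runs a chance cluster
of intact-strain reads splits islands often enough to make tight-boundary
recovery a coin flip — at 99% the margin is decisive, and the quantity
measured is the detector's boundary accuracy rather than Poisson noise.
SNP-exactness uses 50/50 strain pairs at 60×, keeping every truth allele's
expected count far above the calling floor, so precision = recall = 1 is
the deterministic expectation rather than a lucky draw.

## Pipeline

Stages run in dependency order from one YAML config; enabling a stage
without its upstream raises a config error naming the stage. Every output
table carries a header block (package version, config hash, seed); the
config hash excludes the output directory, so the same analysis written
elsewhere hashes identically. All randomness descends from the single
config seed via seed sequences, making reruns byte-identical. Exit codes:
0 success, 2 config error, 1 runtime error.

## Known limitations

- Substitution-only identity math end to end: indel-rich alignments are
  parsed correctly (CIGAR-aware), but the ANI k-mer route fragments across
  indels and will under-report aligned fraction for gappy homology.
- π and pN/pS assume pooled, unlinked pileups; no haplotype phasing or
  linkage statistics.
- Rarefaction detects by mapping-based presence, not per-subsample
  re-assembly, so its curves answer "how many known vOTUs would I still
  detect", not "how many would I have assembled".
- The greedy, seed-anchored clustering can split a chain A–B–C where B
  matches both ends but A and C do not match each other; this is the
  intended behaviour of the longest-as-seed rule, not single linkage.
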