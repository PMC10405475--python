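# brinepop

Downstream viromics for read-mapped viral communities: who is there, how
abundant, which genome regions are strain-variable, who is transcriptionally
active, and what selection pressures act within each population.

`brinepop` is aimed at metagenomics practitioners who already have assembled
contigs, detector score tables and read alignments, and need the inference
layer that turns those into community- and population-level answers:

- **Viral classification** — combine VirSorter categories, DeepVirFinder
  scores and MARVEL probabilities under a four-criterion OR rule
  (category ∈ {1,2,4,5}; DVF ≥ 0.9 & p < 0.05; MARVEL ≥ 90%; or
  DVF ≥ 0.7 & p < 0.05 & MARVEL ≥ 70%).
- **vOTU clustering** — greedy, longest-as-seed clustering of viral contigs
  into species-level units at ≥ 95% nucleotide identity over ≥ 80% of the
  shorter sequence.
- **Abundance profiling** — read filters (≥ 95% identity, ≥ 90% of the read
  aligned), per-base depth, breadth, and mean depth normalized to
  *coverage per gigabase* of virome: `cov/Gb = mean depth × 10⁹ / library bases`.
- **Hypervariable regions (HVRs)** — maximal runs where depth ≤ 20% of the
  contig median, at least 500 bp long, on contigs with median depth ≥ 5×.
- **Activity calling** — a vOTU is putatively active when filtered
  metatranscriptomic reads (90% identity / 90% read coverage) cover ≥ 50%
  of its genome.
- **Macrodiversity** — richness, Shannon `H = −Σ pᵢ ln pᵢ`, shared/unique
  vOTU partitions with their abundance shares, rank-abundance series, and
  seeded rarefaction with the last-four-point slope extrapolation.
- **Microdiversity** — pileup SNP calling (depth ≥ 10, allele count ≥ 4,
  frequency ≥ 1%), nucleotide diversity
  `π = Σ_{a≠b} c_a c_b / (n(n−1))` averaged over eligible sites, SNP
  density per eligible kb, and codon-aware Nei–Gojobori `pN/pS` with
  positive-selection calls (`pN/pS > 1`), plus Wilcoxon rank-sum group
  comparisons.
- **Synthetic communities** — a generator that emulates log-normal
  abundances, strain pools with controlled π and syn/nonsyn mutation mix,
  strain-exclusive replaced regions (HVR analogues), substitution-error
  reads and transcriptome reads, with exact ground truth for every stage.

All of it is importable as a library, drivable stage-by-stage from the
`brinepop` CLI, or runnable end to end from one YAML config.

## Worked example

The demo pipeline simulates one reference community sampled under a
*stable* regime (low strain diversity, target π 0.002, 30% nonsynonymous
mutations) and a *fluctuating* regime (π 0.008–0.01, 70% nonsynonymous),
then runs every stage:

```bash
python analysis/01_run_pipeline.py
```

```text
      group  n_samples  richness  shannon  median_pi  median_snp_density  pct_genes_positive  n_active_votus
fluctuating          2       2.5 0.870876   0.008809           18.873172           73.913043               1
     stable          1       3.0 1.006975   0.002017            4.039637            1.562500               1

median genome pi: stable 0.0020 < fluctuating 0.0088: as designed
```

Reading the table: each row aggregates one sample group. `median_pi` is the
median genome-level nucleotide diversity — the stable group shows ~4× less
intra-population variation than the fluctuating group, and correspondingly
fewer SNPs per eligible kb (`median_snp_density`) and a far smaller share
of genes with `pN/pS > 1` (`pct_genes_positive`), exactly the contrast the
simulation injected. The full table bundle (classification, vOTUs,
abundance per Gb, breadth, HVR BED, per-contig and per-gene microdiversity,
diversity, Venn partition, activity) lands in `results/pipeline/`, each
file stamped with the package version, config hash and seed; rerunning with
the same config and seed reproduces every file byte-for-byte.

The remaining drivers score each inference stage against generator truth,
e.g. π recovery:

```bash
python analysis/02_pi_recovery.py
```

```text
genome  n_strains  target_pi   pi_est  pi_oracle  rel_err
    g1          2      0.001 0.000999   0.001000 0.000860
    g2          3      0.005 0.004985   0.005004 0.003837
    g3          4      0.020 0.019423   0.020005 0.029103
    g4          2      0.005 0.004997   0.005000 0.000528
    g5          3      0.001 0.001019   0.001004 0.014561

max relative error 2.91% (design tolerance: 15%)
```

`pi_oracle` is computed directly from the truth strain sequences
(frequency-weighted pairwise differences), independent of the pileup
estimator being scored.

## Layout

```
src/brinepop/      library: io_formats, synthetic_community, viral_id_votu,
                   coverage_profiles, hvr_detection, microdiversity,
                   community_ecology, validation, pipeline, cli
analysis/          numbered narrative drivers writing results/
scripts/           acceptance.py (validation battery)
tests/             pytest suite
docs/methods.md    models, conventions, parameter rationale, limitations
```
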