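"""Generator contracts: determinism, gene structure, truth bookkeeping."""

import numpy as np
import pytest

from brinepop.codon import CODON_TO_AA, STOP_CODONS, revcomp
from brinepop.synthetic_community import (
    CommunitySpec,
    StrainSpec,
    generate_community,
    generate_genomes,
    inject_strains,
    simulate_reads,
    simulate_transcriptome,
)


def test_generation_is_deterministic_under_seed():
    spec = CommunitySpec(n_genomes=2, genome_len_range=(10_000, 12_000), seed=1)
    a_contigs, a_genes = generate_genomes(spec)
    b_contigs, b_genes = generate_genomes(spec)
    assert [(c.id, c.seq) for c in a_contigs] == [(c.id, c.seq) for c in b_contigs]
    assert [(g.gene_id, g.start, g.end, g.strand) for g in a_genes] == [
        (g.gene_id, g.start, g.end, g.strand) for g in b_genes
    ]


def test_gene_density_and_reading_frames(small_genome):
    contig, genes = small_genome
    # ~1 gene/kb on 30 kb
    assert 25 <= len(genes) <= 35
    for g in genes:
        assert len(g) % 3 == 0
        cds = (
            contig.seq[g.start : g.end]
            if g.strand == "+"
            else revcomp(contig.seq[g.start : g.end])
        )
        assert cds.startswith("ATG")
        assert cds[-3:] in STOP_CODONS
        # no internal stop
        internal = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
        assert all(c in CODON_TO_AA for c in internal)
    # genes do not overlap
    spans = sorted((g.start, g.end) for g in genes)
    assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


def test_invalid_specs_raise():
    with pytest.raises(ValueError):
        CommunitySpec(n_genomes=0)
    with pytest.raises(ValueError):
        CommunitySpec(read_len=50_000)
    with pytest.raises(ValueError):
        StrainSpec(n_strains=2, strain_freqs=[0.7, 0.7])
    with pytest.raises(ValueError):
        StrainSpec(target_pi=0.9)


def test_target_pi_zero_gives_clonal_strains(small_genome):
    contig, genes = small_genome
    strains, truth = inject_strains(
        contig, genes, StrainSpec(n_strains=3, target_pi=0.0), seed=5
    )
    assert truth.true_snps == []
    assert all(s == contig.seq for s in strains)


def test_single_mutated_site_has_half_heterozygosity(small_genome):
    """Two strains at 50/50 differing at one site: expected site π is
    2 * 0.5 * 0.5 = 0.5, so a target of 0.5/L needs exactly one site."""
    contig, genes = small_genome
    L = len(contig)
    strains, truth = inject_strains(
        contig, genes, StrainSpec(n_strains=2, target_pi=0.4 / L), seed=6
    )
    assert len(truth.true_snps) == 1
    snp = truth.true_snps[0]
    assert snp.expected_freq == 0.5
    assert truth.pi_oracle(contig.id) == pytest.approx(0.5 / L)


def test_truth_oracle_matches_target_pi(small_genome):
    contig, genes = small_genome
    for target in (0.001, 0.01):
        _s, truth = inject_strains(
            contig, genes, StrainSpec(n_strains=3, target_pi=target), seed=7
        )
        assert truth.pi_oracle(contig.id) == pytest.approx(target, rel=0.10)


def test_frac_nonsyn_one_labels_all_coding_snps_nonsyn(small_genome):
    contig, genes = small_genome
    _s, truth = inject_strains(
        contig, genes,
        StrainSpec(n_strains=2, target_pi=0.003, frac_nonsyn=1.0, coding_only=True),
        seed=8,
    )
    assert truth.true_snps, "expected injected coding SNPs"
    assert all(s.effect == "nonsynonymous" for s in truth.true_snps)


def test_hvr_interval_must_be_interior(small_genome):
    contig, genes = small_genome
    with pytest.raises(ValueError):
        inject_strains(
            contig, genes,
            StrainSpec(n_strains=2, hvr=(0, 1000, 0.9)), seed=9,
        )


def test_read_count_arithmetic_and_error_free_nm(small_genome):
    contig, genes = small_genome
    L = len(contig)
    fq, recs = simulate_reads([contig.seq], [1.0], contig, 10, 100, 0.0, seed=10)
    assert len(fq) == round(10 * L / 100)
    assert all(r.n_mismatch == 0 for r in recs)
    # fixed seed -> identical output
    fq2, _ = simulate_reads([contig.seq], [1.0], contig, 10, 100, 0.0, seed=10)
    assert fq == fq2


def test_truth_snp_frequencies_realised_in_reads(small_genome):
    """Pooled allele frequency at each truth SNP converges to expected_freq."""
    from brinepop.coverage_profiles import allele_counts

    contig, genes = small_genome
    sspec = StrainSpec(n_strains=2, target_pi=0.002)
    strains, truth = inject_strains(contig, genes, sspec, seed=11)
    _fq, recs = simulate_reads(strains, sspec.strain_freqs, contig, 80, 100, 0.0, seed=12)
    sc = allele_counts(recs, contig)
    code = {b: i for i, b in enumerate("ACGT")}
    for snp in truth.true_snps:
        n = sc.counts[snp.pos].sum()
        f_hat = sc.counts[snp.pos, code[snp.alt]] / n
        # binomial tolerance at depth ~80: 4 sigma
        sigma = np.sqrt(snp.expected_freq * (1 - snp.expected_freq) / n)
        assert abs(f_hat - snp.expected_freq) < 4 * sigma + 1e-9


def test_transcriptome_reads_only_from_active_genes():
    spec = CommunitySpec(n_genomes=2, genome_len_range=(10_000, 12_000), seed=3)
    contigs, genes = generate_genomes(spec)
    fq, recs = simulate_transcriptome(["g1"], contigs, genes, depth=5, read_len=100, seed=4)
    assert fq and all(r.contig_id == "g1" for r in recs)
    gene_spans = [(g.start, g.end) for g in genes if g.contig_id == "g1"]
    for r in recs:
        assert any(s <= r.start and r.end <= e for s, e in gene_spans)
    # empty active set -> no reads
    fq0, recs0 = simulate_transcriptome([], contigs, genes, depth=5, read_len=100, seed=4)
    assert fq0 == [] and recs0 == []
    with pytest.raises(ValueError):
        simulate_transcriptome(["nope"], contigs, genes, depth=5, read_len=100, seed=4)


def test_generate_community_bundles_consistent_truth():
    spec = CommunitySpec(
        n_genomes=3, genome_len_range=(8_000, 10_000), depth_mean=20, seed=21
    )
    comm = generate_community(
        spec, StrainSpec(n_strains=2, target_pi=0.002), active_fraction=0.4
    )
    assert len(comm.contigs) == 3
    assert abs(sum(comm.truth.true_abundances.values()) - 1.0) < 1e-9
    assert comm.truth.active_genomes
    ids = {c.id for c in comm.contigs}
    assert {s.contig_id for s in comm.truth.true_snps} <= ids
    assert all(0 <= s.pos < len(c) for s in comm.truth.true_snps
               for c in comm.contigs if c.id == s.contig_id)
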