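import numpy as np
import pytest

from brinepop.io_formats import Contig, GeneRecord
from brinepop.synthetic_community import (
    CommunitySpec,
    StrainSpec,
    generate_genomes,
    inject_strains,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_genome():
    """One 30 kb genome with ~30 genes, deterministic."""
    spec = CommunitySpec(
        n_genomes=1, genome_len_range=(30_000, 30_000), gene_density=1.0, seed=11
    )
    contigs, genes = generate_genomes(spec)
    return contigs[0], genes


@pytest.fixture(scope="session")
def diverse_pileup(small_genome):
    """Two-strain 50/50 pool at target π 0.005, error-free reads at 60x,
    with filtered allele counts and the truth slice."""
    from brinepop.coverage_profiles import allele_counts, filter_alignments

    contig, genes = small_genome
    sspec = StrainSpec(n_strains=2, target_pi=0.005)
    strains, truth = inject_strains(contig, genes, sspec, seed=12)
    _fq, recs = simulate_reads(
        strains, sspec.strain_freqs, contig, 60, 100, 0.0, seed=13
    )
    sc = allele_counts(filter_alignments(recs), contig)
    return contig, genes, sc, truth


def random_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))
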