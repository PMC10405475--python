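"""Self-validation experiments: run the full inference chain on generated
communities with known truth and score the recovery.

Each experiment is a pure function of its seed, so the same scenario can be
driven from the test suite, the analysis scripts, or the command line. The
scenario parameters are the study conditions of this package's validation
design — genome sizes, depths, strain structures — not knobs to tune per
run; see docs/methods.md for the rationale behind each value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage_profiles import allele_counts, depth_profile, filter_alignments
from .hvr_detection import detect_hvrs
from .io_formats import Contig
from .microdiversity import call_snps, pi, pnps
from .synthetic_community import (
    CommunitySpec,
    StrainSpec,
    generate_genomes,
    inject_strains,
    mutate_copy,
    simulate_reads,
)
from .viral_id_votu import cluster_votus, oracle_ani


@dataclass
class PiRecovery:
    per_genome: list[dict]

    @property
    def max_rel_err(self) -> float:
        return max(g["rel_err"] for g in self.per_genome)


def pi_recovery_experiment(seed: int) -> PiRecovery:
    """Five 50 kb genomes, 2–4 strains, target π in {0.001, 0.005, 0.02},
    50x reads with 0.1% substitution error: pileup π versus the
    truth-strain pairwise oracle."""
    rng = np.random.default_rng(seed)
    spec = CommunitySpec(
        n_genomes=5, genome_len_range=(50_000, 50_000), depth_mean=50,
        error_rate=0.001, seed=int(rng.integers(2**31)),
    )
    contigs, genes = generate_genomes(spec)
    arms = [(2, 0.001), (3, 0.005), (4, 0.02), (2, 0.005), (3, 0.001)]
    rows = []
    for contig, (n_strains, target) in zip(contigs, arms):
        sspec = StrainSpec(n_strains=n_strains, target_pi=target)
        strains, truth = inject_strains(
            contig, genes, sspec, seed=int(rng.integers(2**31))
        )
        _fq, recs = simulate_reads(
            strains, sspec.strain_freqs, contig, spec.depth_mean,
            spec.read_len, spec.error_rate, seed=int(rng.integers(2**31)),
        )
        sc = allele_counts(filter_alignments(recs), contig)
        est = pi(sc, ref_seq=contig.seq)
        oracle = truth.pi_oracle(contig.id)
        rows.append(
            {
                "genome": contig.id,
                "n_strains": n_strains,
                "target_pi": target,
                "pi_est": est,
                "pi_oracle": oracle,
                "rel_err": abs(est - oracle) / oracle,
            }
        )
    return PiRecovery(rows)


@dataclass
class PnpsDirectionality:
    median_high: float  # median gene pN/pS, frac_nonsyn = 0.9 arm
    median_low: float   # frac_nonsyn = 0.1 arm
    positive_fraction_high: float  # share of variant genes with ratio > 1


def pnps_directionality_experiment(seed: int) -> PnpsDirectionality:
    """Two arms on the same 40 kb gene-dense genome at matched mutation
    load (target π 0.004, coding-only): frac_nonsyn 0.9 versus 0.1 at 50x
    error-free coverage."""
    rng = np.random.default_rng(seed)
    spec = CommunitySpec(
        n_genomes=1, genome_len_range=(40_000, 40_000), gene_density=1.0,
        depth_mean=50, seed=int(rng.integers(2**31)),
    )
    contigs, genes = generate_genomes(spec)
    contig = contigs[0]
    medians = {}
    pos_frac = {}
    for frac_nonsyn in (0.9, 0.1):
        sspec = StrainSpec(
            n_strains=2, target_pi=0.004, frac_nonsyn=frac_nonsyn, coding_only=True
        )
        strains, _ = inject_strains(
            contig, genes, sspec, seed=int(rng.integers(2**31))
        )
        _fq, recs = simulate_reads(
            strains, [0.5, 0.5], contig, 50, 100, 0.0,
            seed=int(rng.integers(2**31)),
        )
        sc = allele_counts(filter_alignments(recs), contig)
        calls = call_snps(sc, contig)
        ratios = [pnps(g, calls, sc, contig).ratio for g in genes]
        ratios = [r for r in ratios if not np.isnan(r)]
        medians[frac_nonsyn] = float(np.median(ratios))
        pos_frac[frac_nonsyn] = float(np.mean([r > 1 for r in ratios]))
    return PnpsDirectionality(medians[0.9], medians[0.1], pos_frac[0.9])


@dataclass
class SnpExactness:
    n_truth: int
    n_called: int
    precision: float
    recall: float


def snp_exactness_experiment(seed: int) -> SnpExactness:
    """Error-free reads at 60x from three 40 kb genomes with two strains at
    50/50: the called SNP position set must equal the injected truth."""
    rng = np.random.default_rng(seed)
    spec = CommunitySpec(
        n_genomes=3, genome_len_range=(40_000, 40_000), depth_mean=60,
        error_rate=0.0, seed=int(rng.integers(2**31)),
    )
    contigs, genes = generate_genomes(spec)
    truth_pos: set[tuple[str, int]] = set()
    called_pos: set[tuple[str, int]] = set()
    for contig in contigs:
        sspec = StrainSpec(n_strains=2, target_pi=0.005)
        strains, truth = inject_strains(
            contig, genes, sspec, seed=int(rng.integers(2**31))
        )
        _fq, recs = simulate_reads(
            strains, [0.5, 0.5], contig, 60, 100, 0.0,
            seed=int(rng.integers(2**31)),
        )
        sc = allele_counts(filter_alignments(recs), contig)
        truth_pos |= {(s.contig_id, s.pos) for s in truth.true_snps}
        called_pos |= {(c.contig_id, c.pos) for c in call_snps(sc, contig)}
    tp = len(truth_pos & called_pos)
    return SnpExactness(
        n_truth=len(truth_pos),
        n_called=len(called_pos),
        precision=tp / len(called_pos) if called_pos else float("nan"),
        recall=tp / len(truth_pos) if truth_pos else float("nan"),
    )


@dataclass
class HvrRecovery:
    n_injected: int
    n_detected: int
    recall: float      # truths recovered with both boundaries within 100 bp
    precision: float   # detections overlapping an injected interval
    max_boundary_error: int  # over truths matched by any overlap


def hvr_recovery_experiment(seed: int, n_genomes: int = 20) -> HvrRecovery:
    """One 1–2 kb replaced region per 30 kb genome (99% of strain mass) at
    25x background: detection must recover the islands with tight bounds."""
    rng = np.random.default_rng(seed)
    spec = CommunitySpec(
        n_genomes=n_genomes, genome_len_range=(30_000, 30_000), depth_mean=25,
        error_rate=0.001, seed=int(rng.integers(2**31)),
    )
    contigs, genes = generate_genomes(spec)
    truths: list[tuple[str, int, int]] = []
    dets: list[tuple[str, int, int]] = []
    for contig in contigs:
        h_len = int(rng.integers(1000, 2001))
        h_start = int(rng.integers(3000, len(contig) - 3000 - h_len))
        sspec = StrainSpec(
            n_strains=2, strain_freqs=[0.99, 0.01], target_pi=0.0,
            hvr=(h_start, h_start + h_len, 0.99),
        )
        strains, _truth = inject_strains(
            contig, genes, sspec, seed=int(rng.integers(2**31))
        )
        _fq, recs = simulate_reads(
            strains, sspec.strain_freqs, contig, 25, 100, 0.001,
            seed=int(rng.integers(2**31)),
        )
        prof = depth_profile(filter_alignments(recs), contig)
        truths.append((contig.id, h_start, h_start + h_len))
        dets.extend((contig.id, h.start, h.end) for h in detect_hvrs(prof))
    tight = 0
    berrs = []
    for cid, s, e in truths:
        overlapping = [d for d in dets if d[0] == cid and d[1] < e and s < d[2]]
        if overlapping:
            err = min(max(abs(d[1] - s), abs(d[2] - e)) for d in overlapping)
            berrs.append(err)
            if err <= 100:
                tight += 1
    n_real = sum(
        1
        for d in dets
        if any(t[0] == d[0] and d[1] < t[2] and t[1] < d[2] for t in truths)
    )
    return HvrRecovery(
        n_injected=len(truths),
        n_detected=len(dets),
        recall=tight / len(truths),
        precision=n_real / len(dets) if dets else float("nan"),
        max_boundary_error=max(berrs) if berrs else -1,
    )


def hvr_negative_controls(seed: int) -> tuple[int, int]:
    """Two controls that must yield zero calls: a 400 bp replaced region
    (below the 500 bp size criterion) and a contig at median 4x coverage
    (below the 5x eligibility criterion). Returns the two call counts."""
    rng = np.random.default_rng(seed)
    spec = CommunitySpec(
        n_genomes=1, genome_len_range=(30_000, 30_000), depth_mean=25,
        error_rate=0.0, seed=int(rng.integers(2**31)),
    )
    contigs, genes = generate_genomes(spec)
    contig = contigs[0]
    sspec = StrainSpec(
        n_strains=2, strain_freqs=[0.99, 0.01], target_pi=0.0,
        hvr=(15_000, 15_400, 0.99),
    )
    strains, _ = inject_strains(contig, genes, sspec, seed=int(rng.integers(2**31)))
    _fq, recs = simulate_reads(
        strains, sspec.strain_freqs, contig, 25, 100, 0.0,
        seed=int(rng.integers(2**31)),
    )
    short_run_calls = detect_hvrs(depth_profile(filter_alignments(recs), contig))
    # same strain pool with a full-size island, but sequenced at only 4x
    sspec2 = StrainSpec(
        n_strains=2, strain_freqs=[0.99, 0.01], target_pi=0.0,
        hvr=(15_000, 16_500, 0.99),
    )
    strains2, _ = inject_strains(contig, genes, sspec2, seed=int(rng.integers(2**31)))
    _fq2, recs2 = simulate_reads(
        strains2, sspec2.strain_freqs, contig, 4, 100, 0.0,
        seed=int(rng.integers(2**31)),
    )
    shallow_calls = detect_hvrs(depth_profile(filter_alignments(recs2), contig))
    return len(short_run_calls), len(shallow_calls)


@dataclass
class ClusteringAgreement:
    n_contigs: int
    n_clusters_greedy: int
    n_clusters_oracle: int
    identical: bool


def clustering_oracle_experiment(seed: int, n_bases: int = 8) -> ClusteringAgreement:
    """Fifty-odd synthetic contigs (mutated copies at 0.4/2/8% divergence,
    contained fragments, unrelated sequences): greedy k-mer clustering must
    equal greedy clustering driven by the exhaustive local-DP oracle."""
    rng = np.random.default_rng(seed)

    def rseq(n: int) -> str:
        return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))

    contigs: list[Contig] = []
    k = 0
    for _ in range(n_bases):
        L = int(rng.integers(2000, 5001))
        base = rseq(L)
        contigs.append(Contig(f"c{k:02d}", base)); k += 1
        for rate in (0.004, 0.02, 0.08):
            contigs.append(
                Contig(f"c{k:02d}", mutate_copy(base, int(rate * L),
                                                seed=int(rng.integers(2**31))))
            ); k += 1
        lo = int(rng.integers(0, L // 3))
        contigs.append(Contig(f"c{k:02d}", base[lo : lo + int(L * 0.6)])); k += 1
    while k < 50:
        contigs.append(Contig(f"c{k:02d}", rseq(int(rng.integers(1500, 4000))))); k += 1
    greedy = cluster_votus(contigs)
    oracle = cluster_votus(contigs, ani_fn=oracle_ani)
    as_sets = lambda cls: sorted(tuple(sorted(c.member_ids)) for c in cls)
    return ClusteringAgreement(
        n_contigs=len(contigs),
        n_clusters_greedy=len(greedy),
        n_clusters_oracle=len(oracle),
        identical=as_sets(greedy) == as_sets(oracle),
    )
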