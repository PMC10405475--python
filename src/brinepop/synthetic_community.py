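"""Synthetic virome communities with ground truth for every pipeline stage.

The generator builds multi-genome communities with log-normal abundances,
per-genome strain pools with a controlled expected nucleotide diversity and a
controlled synonymous/nonsynonymous mutation mix, strain-exclusive replaced
regions that behave like hypervariable regions (HVRs), substitution-error
short reads, and transcriptome reads from a declared set of active genomes.
Every stochastic choice flows from one integer seed, and every injected
feature is recorded in a :class:`TruthSet` so downstream inference can be
scored against exact truth.

Mutation placement notes:

* Expected pooled diversity at a site mutated in a strain subset of pooled
  frequency ``f`` is the heterozygosity ``2 f (1 - f)``. Sites are drawn one
  at a time until the accumulated expected heterozygosity reaches
  ``target_pi * L``, so the genome-wide expectation matches ``target_pi``.
* Mutations are kept at least one read length away from contig ends: the
  uniform-start read layout leaves a depth ramp at the ends, and truth
  variants there would be undercovered for reasons that have nothing to do
  with the caller under test.
* Coding mutations are classified against the reference codon at injection
  time; substitutions that would create an internal stop are re-drawn, and
  the start and stop codons themselves are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codon import (
    BASES,
    SENSE_CODONS,
    STOP_CODONS,
    creates_stop,
    revcomp,
    substitution_effect,
)
from .io_formats import AlignmentRecord, Contig, GeneRecord

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunitySpec:
    """Community-level simulation parameters."""

    n_genomes: int = 5
    genome_len_range: tuple[int, int] = (30_000, 60_000)
    gene_density: float = 1.0  # genes per kb
    abundance_mu: float = 0.0  # log-normal parameters of relative abundance
    abundance_sigma: float = 1.0
    read_len: int = 100
    error_rate: float = 0.001
    depth_mean: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        if self.read_len > self.genome_len_range[0]:
            raise ValueError("read_len exceeds minimum genome length")


@dataclass
class StrainSpec:
    """Per-genome strain-pool parameters.

    ``hvr`` is an optional ``(start, end, replaced_strain_fraction)``: the
    interval is replaced with unrelated random sequence in strains making up
    at least that fraction of the pool, so reads from it fail identity
    filters and coverage collapses — the synthetic analogue of an HVR.
    """

    n_strains: int = 2
    strain_freqs: Optional[Sequence[float]] = None
    target_pi: float = 0.0
    frac_nonsyn: float = 0.5
    hvr: Optional[tuple[int, int, float]] = None
    coding_only: bool = False  # place all mutations inside genes

    def __post_init__(self) -> None:
        if not 0 <= self.target_pi < 0.75:
            raise ValueError("target_pi must be in [0, 0.75)")
        if self.strain_freqs is None:
            self.strain_freqs = [1.0 / self.n_strains] * self.n_strains
        freqs = np.asarray(self.strain_freqs, dtype=float)
        if len(freqs) != self.n_strains or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("strain_freqs must have n_strains entries summing to 1")


@dataclass
class TruthSNP:
    contig_id: str
    pos: int
    ref: str
    alt: str
    expected_freq: float
    effect: str  # synonymous | nonsynonymous | noncoding
    gene_id: Optional[str] = None


@dataclass
class TruthSet:
    """Simulation ground truth consumed by tests and acceptance checks."""

    true_abundances: dict[str, float] = field(default_factory=dict)
    true_snps: list[TruthSNP] = field(default_factory=list)
    true_hvrs: list[tuple[str, int, int]] = field(default_factory=list)
    active_genomes: set[str] = field(default_factory=set)
    strain_seqs: dict[str, list[str]] = field(default_factory=dict)
    strain_freqs: dict[str, list[float]] = field(default_factory=dict)

    def snps_for(self, contig_id: str) -> list[TruthSNP]:
        return [s for s in self.true_snps if s.contig_id == contig_id]

    def pi_oracle(self, contig_id: str) -> float:
        """Genome π from truth strains: freq-weighted mean pairwise difference.

        Direct oracle, independent of the pileup estimator: for every ordered
        strain pair (i, j), i != j, add ``f_i f_j d_ij / L``.
        """
        seqs = self.strain_seqs[contig_id]
        freqs = self.strain_freqs[contig_id]
        arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
        L = len(arrs[0])
        total = 0.0
        for i in range(len(arrs)):
            for j in range(len(arrs)):
                if i == j:
                    continue
                d = int(np.count_nonzero(arrs[i] != arrs[j]))
                total += freqs[i] * freqs[j] * d
        return total / L


# ---------------------------------------------------------------------------
# genomes and genes


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASE_ARR[rng.integers(0, 4, size=length)]


def generate_genomes(
    spec: CommunitySpec,
) -> tuple[list[Contig], list[GeneRecord]]:
    """Random genomes with non-overlapping coding genes.

    Genes are ``ATG`` + sense codons + stop, length divisible by 3, placed on
    either strand, at least one read length away from contig ends.
    Deterministic under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    contigs: list[Contig] = []
    genes: list[GeneRecord] = []
    for gi in range(spec.n_genomes):
        L = int(rng.integers(spec.genome_len_range[0], spec.genome_len_range[1] + 1))
        arr = _random_seq(rng, L)
        cid = f"g{gi + 1}"
        n_genes = int(round(spec.gene_density * L / 1000.0))
        lo, hi = spec.read_len, L - spec.read_len
        occupied: list[tuple[int, int]] = []
        placed = 0
        attempts = 0
        while placed < n_genes:
            attempts += 1
            if attempts > 200 * max(n_genes, 1):
                raise ValueError(
                    f"cannot place {n_genes} genes on {cid}: gene density infeasible"
                )
            n_codons = int(rng.integers(100, 300))  # 300–900 bp coding body
            glen = 3 * (n_codons + 2)
            if hi - lo < glen:
                continue
            start = int(rng.integers(lo, hi - glen + 1))
            end = start + glen
            if any(s < end and start < e for s, e in occupied):
                continue
            occupied.append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            body = "".join(
                SENSE_CODONS[k]
                for k in rng.integers(0, len(SENSE_CODONS), size=n_codons)
            )
            stop = sorted(STOP_CODONS)[int(rng.integers(0, 3))]
            cds = "ATG" + body + stop
            insert = cds if strand == "+" else revcomp(cds)
            arr[start:end] = np.frombuffer(insert.encode(), dtype=np.uint8)
            genes.append(
                GeneRecord(
                    gene_id=f"{cid}_gene{placed + 1}",
                    contig_id=cid,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
            placed += 1
        contigs.append(Contig(id=cid, seq=arr.tobytes().decode()))
    return contigs, genes


# ---------------------------------------------------------------------------
# strain pools


def _codon_context(
    gene: GeneRecord, seq: str, pos: int
) -> tuple[str, int, bool]:
    """Reference codon containing ``pos``, offset of pos within it, and
    whether pos falls in the start or stop codon. Codons are read on the
    gene's strand."""
    if gene.strand == "+":
        off = pos - gene.start
        ci = off // 3
        codon = seq[gene.start + 3 * ci : gene.start + 3 * ci + 3]
        within = off % 3
    else:
        off = gene.end - 1 - pos
        ci = off // 3
        codon = revcomp(seq[gene.end - 3 * ci - 3 : gene.end - 3 * ci])
        within = off % 3
    n_codons = len(gene) // 3
    terminal = ci == 0 or ci == n_codons - 1
    return codon, within, terminal


def inject_strains(
    genome: Contig,
    genes: Sequence[GeneRecord],
    strain_spec: StrainSpec,
    seed: int,
    read_len: int = 100,
) -> tuple[list[str], TruthSet]:
    """Derive a strain pool from a reference genome.

    Returns the strain sequences (parallel to ``strain_spec.strain_freqs``)
    and a TruthSet slice holding the injected SNPs and HVR for this genome.
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    seq = genome.seq
    freqs = list(map(float, strain_spec.strain_freqs))
    n_strains = strain_spec.n_strains
    strain_arrs = [
        np.frombuffer(seq.encode(), dtype=np.uint8).copy() for _ in range(n_strains)
    ]
    truth = TruthSet()
    my_genes = [g for g in genes if g.contig_id == genome.id]

    hvr_interval: Optional[tuple[int, int]] = None
    if strain_spec.hvr is not None:
        h_start, h_end, h_frac = strain_spec.hvr
        if h_start <= 0 or h_end >= L or h_end <= h_start:
            raise ValueError(
                f"HVR interval ({h_start}, {h_end}) overlaps an end of {genome.id}"
            )
        hvr_interval = (h_start, h_end)
        # smallest strain prefix whose mass reaches the requested fraction
        order = np.argsort(freqs)[::-1]
        mass = 0.0
        for si in order:
            if mass >= h_frac - 1e-9:
                break
            strain_arrs[si][h_start:h_end] = _random_seq(rng, h_end - h_start)
            mass += freqs[si]
        truth.true_hvrs.append((genome.id, h_start, h_end))

    # per-position gene lookup
    gene_at: dict[int, GeneRecord] = {}
    for g in my_genes:
        for p in range(g.start, g.end):
            gene_at[p] = g

    h_target = strain_spec.target_pi * L
    h_acc = 0.0
    used: set[int] = set()
    guard = 0
    while h_acc < h_target:
        guard += 1
        if guard > 50 * L:
            raise ValueError("target_pi infeasible for this genome")
        if strain_spec.coding_only:
            g = my_genes[int(rng.integers(0, len(my_genes)))]
            pos = int(rng.integers(g.start, g.end))
        else:
            pos = int(rng.integers(read_len, L - read_len))
        if pos in used:
            continue
        if hvr_interval and hvr_interval[0] - read_len <= pos < hvr_interval[1] + read_len:
            continue
        ref_base = seq[pos]
        gene = gene_at.get(pos)
        if gene is not None:
            codon, within, terminal = _codon_context(gene, seq, pos)
            if terminal or codon in STOP_CODONS:
                continue
            # the substituted base as seen by the codon (gene strand)
            want_nonsyn = rng.random() < strain_spec.frac_nonsyn
            wanted = "nonsynonymous" if want_nonsyn else "synonymous"
            candidates = []
            for b in BASES:
                if b == ref_base:
                    continue
                b_codon = b if gene.strand == "+" else revcomp(b)
                if creates_stop(codon, within, b_codon):
                    continue
                if substitution_effect(codon, within, b_codon) == wanted:
                    candidates.append(b)
            if not candidates:
                continue  # redraw a new site
            alt = candidates[int(rng.integers(0, len(candidates)))]
            effect = wanted
            gene_id = gene.gene_id
        else:
            alt = BASES[int(rng.integers(0, 4))]
            while alt == ref_base:
                alt = BASES[int(rng.integers(0, 4))]
            effect = "noncoding"
            gene_id = None
        # nonempty proper strain subset
        while True:
            mask = rng.random(n_strains) < 0.5
            if 0 < mask.sum() < n_strains:
                break
        f = float(np.dot(mask, freqs))
        alt_byte = ord(alt)
        for si in range(n_strains):
            if mask[si]:
                strain_arrs[si][pos] = alt_byte
        used.add(pos)
        truth.true_snps.append(
            TruthSNP(genome.id, pos, ref_base, alt, f, effect, gene_id)
        )
        h_acc += 2.0 * f * (1.0 - f)

    strains = [a.tobytes().decode() for a in strain_arrs]
    truth.strain_seqs[genome.id] = strains
    truth.strain_freqs[genome.id] = freqs
    return strains, truth


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    strains: Sequence[str],
    freqs: Sequence[float],
    reference: Contig,
    depth_mean: float,
    read_len: int,
    error_rate: float,
    seed: int,
) -> tuple[list[tuple[str, str]], list[AlignmentRecord]]:
    """Uniform-start substitution-error reads from a strain pool.

    Returns FASTQ-ready ``(read_id, sequence-as-sequenced)`` pairs and truth
    alignment records placing each read at its exact origin, with
    NM = injected errors + strain-versus-reference mismatches in the window.
    Read count is ``round(depth_mean * L / read_len)``.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    L = len(reference)
    if read_len > L:
        raise ValueError("read_len exceeds genome length")
    rng = np.random.default_rng(seed)
    ref_arr = np.frombuffer(reference.seq.encode(), dtype=np.uint8)
    strain_arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in strains]
    n_reads = int(round(depth_mean * L / read_len))
    strain_idx = rng.choice(len(strains), size=n_reads, p=np.asarray(freqs, float))
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    fastq: list[tuple[str, str]] = []
    records: list[AlignmentRecord] = []
    for i in range(n_reads):
        s, st = int(strain_idx[i]), int(starts[i])
        window = strain_arrs[s][st : st + read_len].copy()
        if error_rate > 0:
            err = rng.random(read_len) < error_rate
            n_err = int(err.sum())
            if n_err:
                window[err] = _BASE_ARR[
                    (
                        np.searchsorted(_BASE_ARR, window[err])
                        + rng.integers(1, 4, size=n_err)
                    )
                    % 4
                ]
        nm = int(np.count_nonzero(window != ref_arr[st : st + read_len]))
        fwd = window.tobytes().decode()
        rid = f"{reference.id}_r{i}"
        minus = bool(strands[i])
        fastq.append((rid, revcomp(fwd) if minus else fwd))
        records.append(
            AlignmentRecord(
                read_id=rid,
                contig_id=reference.id,
                start=st,
                cigar=[("M", read_len)],
                n_mismatch=nm,
                read_len=read_len,
                mapped=True,
                strand="-" if minus else "+",
                seq=fwd,
            )
        )
    return fastq, records


def simulate_transcriptome(
    active_ids: Sequence[str],
    contigs: Sequence[Contig],
    genes: Sequence[GeneRecord],
    depth: float,
    read_len: int,
    seed: int,
    error_rate: float = 0.0,
) -> tuple[list[tuple[str, str]], list[AlignmentRecord]]:
    """Transcriptome reads drawn only from gene intervals of active genomes.

    Non-active genomes receive zero reads. ``depth`` is the target depth over
    the genic bases of each active genome. Genomes with no annotated genes
    are skipped with a warning.
    """
    import warnings

    by_contig = {c.id: c for c in contigs}
    unknown = set(active_ids) - set(by_contig)
    if unknown:
        raise ValueError(f"active ids not in community: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    fastq: list[tuple[str, str]] = []
    records: list[AlignmentRecord] = []
    for cid in active_ids:
        contig = by_contig[cid]
        my_genes = [
            g for g in genes if g.contig_id == cid and len(g) >= read_len
        ]
        if not my_genes:
            warnings.warn(f"active genome {cid!r} has no usable genes; skipped")
            continue
        ref_arr = np.frombuffer(contig.seq.encode(), dtype=np.uint8)
        glens = np.array([len(g) for g in my_genes], dtype=float)
        total = glens.sum()
        n_reads = int(round(depth * total / read_len))
        gene_idx = rng.choice(len(my_genes), size=n_reads, p=glens / total)
        for i in range(n_reads):
            g = my_genes[int(gene_idx[i])]
            st = int(rng.integers(g.start, g.end - read_len + 1))
            window = ref_arr[st : st + read_len].copy()
            if error_rate > 0:
                err = rng.random(read_len) < error_rate
                n_err = int(err.sum())
                if n_err:
                    window[err] = _BASE_ARR[
                        (
                            np.searchsorted(_BASE_ARR, window[err])
                            + rng.integers(1, 4, size=n_err)
                        )
                        % 4
                    ]
            nm = int(np.count_nonzero(window != ref_arr[st : st + read_len]))
            fwd = window.tobytes().decode()
            rid = f"{cid}_t{i}"
            fastq.append((rid, fwd))
            records.append(
                AlignmentRecord(
                    read_id=rid,
                    contig_id=cid,
                    start=st,
                    cigar=[("M", read_len)],
                    n_mismatch=nm,
                    read_len=read_len,
                    seq=fwd,
                )
            )
    return fastq, records


# ---------------------------------------------------------------------------
# whole communities


@dataclass
class Community:
    """A fully generated community plus its ground truth."""

    spec: CommunitySpec
    contigs: list[Contig]
    genes: list[GeneRecord]
    truth: TruthSet
    reads: list[tuple[str, str]]
    alignments: list[AlignmentRecord]


def generate_community(
    spec: CommunitySpec,
    strain_specs: Optional[dict[str, StrainSpec] | StrainSpec] = None,
    active_fraction: float = 0.0,
) -> Community:
    """Generate genomes, strain pools, abundances and reads in one call.

    ``strain_specs`` may be a single StrainSpec applied to every genome or a
    dict keyed by genome id; genomes without a spec stay clonal. Per-genome
    depth is ``depth_mean`` scaled by the genome's log-normal relative
    abundance (so the community average stays at ``depth_mean``).
    """
    rng = np.random.default_rng(spec.seed)
    contigs, genes = generate_genomes(spec)
    raw = rng.lognormal(spec.abundance_mu, spec.abundance_sigma, size=spec.n_genomes)
    rel = raw / raw.sum()
    truth = TruthSet(true_abundances={c.id: float(a) for c, a in zip(contigs, rel)})
    reads: list[tuple[str, str]] = []
    alns: list[AlignmentRecord] = []
    for i, contig in enumerate(contigs):
        if isinstance(strain_specs, StrainSpec):
            sspec = strain_specs
        elif strain_specs:
            sspec = strain_specs.get(contig.id, StrainSpec(n_strains=1, strain_freqs=[1.0]))
        else:
            sspec = StrainSpec(n_strains=1, strain_freqs=[1.0])
        strains, slice_truth = inject_strains(
            contig, genes, sspec, seed=int(rng.integers(2**31)), read_len=spec.read_len
        )
        truth.true_snps.extend(slice_truth.true_snps)
        truth.true_hvrs.extend(slice_truth.true_hvrs)
        truth.strain_seqs.update(slice_truth.strain_seqs)
        truth.strain_freqs.update(slice_truth.strain_freqs)
        depth_i = spec.depth_mean * rel[i] * spec.n_genomes
        fq, recs = simulate_reads(
            strains,
            sspec.strain_freqs,
            contig,
            depth_i,
            spec.read_len,
            spec.error_rate,
            seed=int(rng.integers(2**31)),
        )
        reads.extend(fq)
        alns.extend(recs)
    if active_fraction > 0:
        n_active = max(1, int(round(active_fraction * spec.n_genomes)))
        active = [c.id for c in contigs[:n_active]]
        truth.active_genomes = set(active)
    return Community(spec, contigs, genes, truth, reads, alns)


# -- fixtures for clustering tests ------------------------------------------


def mutate_copy(seq: str, n_subs: int, seed: int, evenly: bool = False) -> str:
    """A copy of ``seq`` with ``n_subs`` substitutions (evenly spaced or
    random distinct positions). Used to build clustering fixtures with a
    known identity."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if evenly:
        positions = np.linspace(0, len(seq) - 1, n_subs).astype(int)
    else:
        positions = rng.choice(len(seq), size=n_subs, replace=False)
    for p in positions:
        old = arr[p]
        new = old
        while new == old:
            new = _BASE_ARR[int(rng.integers(0, 4))]
        arr[p] = new
    return arr.tobytes().decode()
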