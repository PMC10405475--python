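"""Intra-population statistics: SNP calling, nucleotide diversity π, SNP
density, codon-aware pN/pS with selection classes, and group comparisons.

Conventions
-----------
* A site is *eligible* when its pileup depth reaches ``min_cov`` (default
  10x). An allele is reported as a variant when it differs from the site
  consensus and clears both an absolute count (``min_count``, default 4)
  and a frequency (``min_freq``, default 0.01) threshold. The consensus is
  the most frequent allele, ties broken toward the reference base.
* π at a site is the unbiased pairwise-difference estimator
  ``sum_{a != b} c_a c_b / (n (n - 1))``; region π is the mean of site π
  over eligible sites. Site counts are first *denoised*: alleles that fail
  the variant thresholds are removed (the consensus always stays), so
  sequencing errors scattered below the calling floor do not inflate π.
* pN/pS is Nei–Gojobori style: observed nonsynonymous/synonymous changes
  (each reported alt allele counted once, classified by substituting it
  into the reference codon on the gene's strand), normalized by synonymous
  and nonsynonymous site totals summed over codons whose three positions
  are all eligible. A gene with variants but no synonymous ones gets the
  pseudocount ratio ``(N_obs + 1) / (S_obs + 1)`` on the observed counts
  only, flagged in the output. pN/pS > 1 is classed as positive selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon import BASES, CODON_TO_AA, revcomp, substitution_effect
from .coverage_profiles import SiteCounts
from .io_formats import Contig, GeneRecord

_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class SNPCall:
    contig_id: str
    pos: int
    ref_allele: str
    consensus: str
    alts: list[tuple[str, int, float]]  # (base, count, frequency)
    site_depth: int
    effects: dict[str, dict[str, str]] = field(default_factory=dict)
    # effects[gene_id][alt_base] -> synonymous | nonsynonymous


def denoised_counts(
    sc: SiteCounts,
    ref_seq: str,
    min_cov: int = 10,
    min_count: int = 4,
    min_freq: float = 0.01,
) -> np.ndarray:
    """Counts with sub-threshold alleles zeroed; consensus always kept.

    Sites below ``min_cov`` are zeroed entirely (ineligible).
    """
    counts = sc.counts.astype(np.int64).copy()
    depth = counts.sum(axis=1)
    eligible = depth >= min_cov
    counts[~eligible] = 0
    cons = _consensus_codes(counts, ref_seq)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / np.maximum(depth, 1)[:, None]
    keep = (counts >= min_count) & (freq >= min_freq)
    rows = np.arange(len(counts))
    keep[rows[eligible], cons[eligible]] = True
    return np.where(keep, counts, 0)


def _consensus_codes(counts: np.ndarray, ref_seq: str) -> np.ndarray:
    """Per-site consensus allele code; ties broken toward the reference."""
    ref_codes = np.array(
        [_BASE_TO_CODE.get(b, 0) for b in ref_seq], dtype=np.int64
    )
    maxc = counts.max(axis=1)
    cons = counts.argmax(axis=1)
    ref_is_max = counts[np.arange(len(counts)), ref_codes] == maxc
    return np.where(ref_is_max, ref_codes, cons)


def call_snps(
    sc: SiteCounts,
    contig: Contig,
    min_cov: int = 10,
    min_count: int = 4,
    min_freq: float = 0.01,
) -> list[SNPCall]:
    """Call variant sites from pileup allele counts.

    Multi-allelic sites yield one call carrying every passing alt.
    """
    counts = sc.counts
    depth = counts.sum(axis=1)
    eligible = depth >= min_cov
    cons = _consensus_codes(counts, contig.seq)
    calls: list[SNPCall] = []
    cand = np.nonzero(eligible)[0]
    for pos in cand:
        n = int(depth[pos])
        alts = []
        for code in range(4):
            if code == cons[pos]:
                continue
            c = int(counts[pos, code])
            if c >= min_count and c / n >= min_freq:
                alts.append((BASES[code], c, c / n))
        if alts:
            calls.append(
                SNPCall(
                    contig_id=sc.contig_id,
                    pos=int(pos),
                    ref_allele=contig.seq[pos],
                    consensus=BASES[int(cons[pos])],
                    alts=alts,
                    site_depth=n,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# π and SNP density


def pi(
    sc: SiteCounts,
    region: Optional[tuple[int, int]] = None,
    min_cov: int = 10,
    min_count: int = 4,
    min_freq: float = 0.01,
    ref_seq: Optional[str] = None,
) -> float:
    """Region nucleotide diversity: mean site π over eligible sites.

    Returns NaN when the region has no eligible sites. ``ref_seq`` (full
    contig) is needed for consensus tie-breaking during denoising; when
    omitted, ties go to the lowest base code.
    """
    counts = denoised_counts(
        sc, ref_seq if ref_seq is not None else "A" * len(sc.counts),
        min_cov, min_count, min_freq,
    )
    if region is not None:
        counts = counts[region[0] : region[1]]
    n = counts.sum(axis=1)
    eligible = n >= min_cov
    if not eligible.any():
        return float("nan")
    c = counts[eligible].astype(float)
    ne = n[eligible].astype(float)
    sum_sq = (c**2).sum(axis=1)
    site_pi = (ne**2 - sum_sq) / (ne * (ne - 1.0))
    return float(site_pi.mean())


def eligible_sites(
    sc: SiteCounts, region: Optional[tuple[int, int]] = None, min_cov: int = 10
) -> int:
    depth = sc.depth
    if region is not None:
        depth = depth[region[0] : region[1]]
    return int(np.count_nonzero(depth >= min_cov))


def snp_density(n_snps: int, n_eligible: int) -> float:
    """SNPs per kilobase of eligible sites (NaN when none are eligible)."""
    if n_eligible <= 0:
        return float("nan")
    return n_snps / (n_eligible / 1000.0)


def genes_with_snp_fraction(
    genes: Sequence[GeneRecord],
    snp_calls: Sequence[SNPCall],
    sc: SiteCounts,
    min_cov: int = 10,
) -> float:
    """Fraction of genes (with >= 1 eligible site) carrying >= 1 SNP."""
    snp_pos = {(s.contig_id, s.pos) for s in snp_calls}
    n_assessed = 0
    n_with = 0
    for g in genes:
        if g.contig_id != sc.contig_id:
            continue
        if eligible_sites(sc, (g.start, g.end), min_cov) == 0:
            continue
        n_assessed += 1
        if any((g.contig_id, p) in snp_pos for p in range(g.start, g.end)):
            n_with += 1
    return n_with / n_assessed if n_assessed else float("nan")


# ---------------------------------------------------------------------------
# Nei–Gojobori sites and pN/pS


def ng_sites(codon: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous site counts of one sense codon.

    Each of the nine single-base mutants is classified by the genetic code;
    ``s_sites`` is the per-position fraction of synonymous changes summed
    over the three positions, ``n_sites = 3 - s_sites``. Mutants creating a
    stop codon count as nonsynonymous.
    """
    if codon not in CODON_TO_AA:
        raise ValueError(f"{codon!r} is not a sense codon")
    s = 0.0
    for pos in range(3):
        syn = sum(
            1
            for b in BASES
            if b != codon[pos]
            and substitution_effect(codon, pos, b) == "synonymous"
        )
        s += syn / 3.0
    return 3.0 - s, s


@dataclass
class GeneSelection:
    gene_id: str
    contig_id: str
    n_obs: int
    s_obs: int
    n_sites: float
    s_sites: float
    pn: float
    ps: float
    ratio: float
    selection: str  # positive | purifying | no-variation
    flag: str = ""  # "pseudocount" when the S_obs=0 rule applied


def classify_snp_effects(
    gene: GeneRecord, snp_calls: Sequence[SNPCall], contig: Contig
) -> None:
    """Annotate each call inside ``gene`` with per-allele syn/nonsyn effects
    (stored on the call, keyed by gene id).

    Each segregating allele differing from the *reference* base counts as
    one mutation, classified by substituting it into the reference codon.
    The consensus is included: when the derived allele has risen past 50%
    frequency the reported variant is the reference base itself, but the
    segregating change is still consensus-versus-reference.
    """
    for call in snp_calls:
        if call.contig_id != gene.contig_id or not gene.start <= call.pos < gene.end:
            continue
        if gene.strand == "+":
            off = call.pos - gene.start
        else:
            off = gene.end - 1 - call.pos
        ci, within = divmod(off, 3)
        if gene.strand == "+":
            codon = contig.seq[gene.start + 3 * ci : gene.start + 3 * ci + 3]
        else:
            codon = revcomp(contig.seq[gene.end - 3 * ci - 3 : gene.end - 3 * ci])
        if codon not in CODON_TO_AA:
            continue  # reference stop/ambiguous codon: skip
        ref_base = contig.seq[call.pos]
        segregating = {a for a, _c, _f in call.alts} | {call.consensus}
        effects = {}
        for allele in sorted(segregating - {ref_base}):
            allele_in_codon = allele if gene.strand == "+" else revcomp(allele)
            effects[allele] = substitution_effect(codon, within, allele_in_codon)
        call.effects[gene.gene_id] = effects


def pnps(
    gene: GeneRecord,
    snp_calls: Sequence[SNPCall],
    sc: SiteCounts,
    contig: Contig,
    min_cov: int = 10,
) -> GeneSelection:
    """Gene pN/pS and selection class from called variants.

    Site totals sum over codons whose three positions are all eligible;
    observed counts sum each reported alt allele once. Genes whose reference
    frame contains an internal stop are rejected.
    """
    if len(gene) % 3 != 0:
        raise ValueError(f"gene {gene.gene_id!r} length not divisible by 3")
    cds = (
        contig.seq[gene.start : gene.end]
        if gene.strand == "+"
        else revcomp(contig.seq[gene.start : gene.end])
    )
    n_codons = len(cds) // 3
    for ci in range(n_codons - 1):
        if cds[3 * ci : 3 * ci + 3] not in CODON_TO_AA and "N" not in cds[3 * ci : 3 * ci + 3]:
            raise ValueError(f"gene {gene.gene_id!r} has internal stop in reference")
    depth = sc.depth
    n_sum = 0.0
    s_sum = 0.0
    for ci in range(n_codons):
        codon = cds[3 * ci : 3 * ci + 3]
        if codon not in CODON_TO_AA:
            continue  # stop codon or N: skipped
        if gene.strand == "+":
            span = (gene.start + 3 * ci, gene.start + 3 * ci + 3)
        else:
            span = (gene.end - 3 * ci - 3, gene.end - 3 * ci)
        if not (depth[span[0] : span[1]] >= min_cov).all():
            continue
        n_i, s_i = ng_sites(codon)
        n_sum += n_i
        s_sum += s_i
    classify_snp_effects(gene, snp_calls, contig)
    n_obs = 0
    s_obs = 0
    for call in snp_calls:
        eff = call.effects.get(gene.gene_id)
        if not eff:
            continue
        for alt_effect in eff.values():
            if alt_effect == "nonsynonymous":
                n_obs += 1
            else:
                s_obs += 1
    if n_obs + s_obs == 0:
        return GeneSelection(
            gene.gene_id, gene.contig_id, 0, 0, n_sum, s_sum,
            0.0, 0.0, float("nan"), "no-variation",
        )
    flag = ""
    if s_obs == 0:
        # pseudocount on observed counts only; sites untouched
        pn = (n_obs + 1) / n_sum if n_sum else float("nan")
        ps = (s_obs + 1) / s_sum if s_sum else float("nan")
        flag = "pseudocount"
    else:
        pn = n_obs / n_sum if n_sum else float("nan")
        ps = s_obs / s_sum if s_sum else float("nan")
    ratio = pn / ps if ps and not np.isnan(ps) else float("nan")
    selection = "positive" if ratio > 1 else "purifying"
    return GeneSelection(
        gene.gene_id, gene.contig_id, n_obs, s_obs, n_sum, s_sum,
        pn, ps, ratio, selection, flag,
    )


# ---------------------------------------------------------------------------
# summaries and comparisons


def contig_summary(
    sc: SiteCounts,
    contig: Contig,
    genes: Sequence[GeneRecord],
    min_cov: int = 10,
    min_count: int = 4,
    min_freq: float = 0.01,
) -> tuple[dict, pd.DataFrame]:
    """Per-contig and per-gene microdiversity tables for one contig."""
    calls = call_snps(sc, contig, min_cov, min_count, min_freq)
    n_elig = eligible_sites(sc, min_cov=min_cov)
    row = {
        "contig_id": contig.id,
        "pi": pi(sc, min_cov=min_cov, min_count=min_count, min_freq=min_freq,
                 ref_seq=contig.seq),
        "n_snps": len(calls),
        "snp_density": snp_density(len(calls), n_elig),
        "eligible_sites": n_elig,
    }
    my_genes = [g for g in genes if g.contig_id == contig.id]
    row["genes_with_snp_fraction"] = genes_with_snp_fraction(
        my_genes, calls, sc, min_cov
    )
    gene_rows = []
    for g in my_genes:
        sel = pnps(g, calls, sc, contig, min_cov)
        g_elig = eligible_sites(sc, (g.start, g.end), min_cov)
        n_gene_snps = sum(1 for c in calls if g.start <= c.pos < g.end)
        gene_rows.append(
            {
                "gene_id": g.gene_id,
                "contig_id": g.contig_id,
                "pi": pi(sc, (g.start, g.end), min_cov, min_count, min_freq,
                         ref_seq=contig.seq),
                "snp_density": snp_density(n_gene_snps, g_elig),
                "pN": sel.pn,
                "pS": sel.ps,
                "pnps": sel.ratio,
                "selection": sel.selection,
                "flag": sel.flag,
            }
        )
    return row, pd.DataFrame(gene_rows)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between groups.

    Input values are per-contig or per-gene statistics; NaN entries are
    dropped. Raises if any group is empty after that.
    """
    groups = {
        k: np.asarray([v for v in vals if not np.isnan(v)], dtype=float)
        for k, vals in values_by_group.items()
    }
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for k, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"group {k!r} has no defined values")
    names = list(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "median_a": float(np.median(a)),
                    "median_b": float(np.median(b)),
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


def snps_to_vcf(calls: Sequence[SNPCall]) -> str:
    """VCF-style text (CHROM, 1-based POS, REF, ALT, INFO DP/AF/EFFECT)."""
    lines = ["##fileformat=VCFv4.2", "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for c in calls:
        alts = ",".join(a for a, _, _ in c.alts)
        afs = ",".join(f"{f:.4f}" for _, _, f in c.alts)
        effs = []
        for gid, eff in c.effects.items():
            for alt, e in eff.items():
                effs.append(f"{gid}:{alt}:{e}")
        info = f"DP={c.site_depth};AF={afs}"
        if effs:
            info += ";EFFECT=" + ",".join(effs)
        lines.append(
            f"{c.contig_id}\t{c.pos + 1}\t.\t{c.consensus}\t{alts}\t.\tPASS\t{info}"
        )
    return "\n".join(lines) + "\n"
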