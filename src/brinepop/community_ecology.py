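"""Macrodiversity and community comparison: Shannon diversity, shared/unique
vOTU partitions, rank-abundance series, rarefaction with slope extrapolation,
and metatranscriptomic activity calling.

Presence of a vOTU in a sample defaults to breadth >= 0.70 at depth >= 1.
Activity follows the 90/90/50 triple: transcript reads filtered at 90%
identity and 90% read fraction, a vOTU called active when they cover at
least 50% of its genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .coverage_profiles import (
    DepthProfile,
    breadth,
    depth_profile,
    filter_alignments,
)
from .io_formats import AlignmentRecord, Contig, GeneRecord


def shannon(abundances: Sequence[float], base: Optional[float] = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive entries.

    Natural log by default; ``base`` switches the logarithm. Zero entries
    contribute nothing, so padding a community with absent vOTUs leaves H
    unchanged.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("all-zero abundance vector")
    p = a / a.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def presence_matrix(
    breadth_by_sample: Mapping[str, Mapping[str, float]],
    min_breadth: float = 0.70,
) -> pd.DataFrame:
    """Boolean vOTU x sample matrix from per-sample breadth values."""
    samples = list(breadth_by_sample)
    votus = sorted({v for s in samples for v in breadth_by_sample[s]})
    data = {
        s: [breadth_by_sample[s].get(v, 0.0) >= min_breadth for v in votus]
        for s in samples
    }
    return pd.DataFrame(data, index=votus)


def shared_unique(
    presence: pd.DataFrame,
    samples: Sequence[str],
    rel_abundance: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Venn-region vOTU counts (2 or 3 samples) with per-sample summed
    relative abundance of each region's vOTUs."""
    for s in samples:
        if s not in presence.columns:
            raise ValueError(f"unknown sample {s!r}")
    if not 2 <= len(samples) <= 3:
        raise ValueError("shared_unique handles 2 or 3 samples")
    rows = []
    n = len(samples)
    for r in range(1, n + 1):
        for members in combinations(samples, r):
            inside = presence[list(members)].all(axis=1)
            outside = ~presence[[s for s in samples if s not in members]].any(axis=1) \
                if r < n else pd.Series(True, index=presence.index)
            region = presence.index[inside & outside]
            row = {
                "region": "&".join(members),
                "n_votus": len(region),
            }
            if rel_abundance is not None:
                for s in samples:
                    row[f"abundance_{s}"] = float(
                        rel_abundance.loc[region, s].sum()
                    ) if len(region) else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def rank_abundance(
    rel_abundance: pd.DataFrame, order_by_sample: str, other_sample: str
) -> pd.DataFrame:
    """Rank-abundance series ordered by one sample, with the other sample's
    exclusive vOTUs appended by their own abundance.

    Ties break by lexicographic vOTU id.
    """
    ra = rel_abundance
    in_ref = ra[order_by_sample] > 0
    ref_part = ra.loc[in_ref].sort_values(
        [order_by_sample], ascending=False, kind="mergesort"
    )
    # stable sort then tie-break on id
    ref_part = ref_part.iloc[
        np.lexsort((ref_part.index.astype(str), -ref_part[order_by_sample].values))
    ]
    excl = ra.loc[(~in_ref) & (ra[other_sample] > 0)]
    excl = excl.iloc[
        np.lexsort((excl.index.astype(str), -excl[other_sample].values))
    ]
    out = pd.concat([ref_part, excl])
    out = out[[order_by_sample, other_sample]].copy()
    out["rank"] = np.arange(1, len(out) + 1)
    out["exclusive"] = [not in_ref.get(v, False) for v in out.index]
    return out


@dataclass
class RarefactionCurve:
    points: list[tuple[int, int]]  # (reads subsampled, vOTUs detected)
    slope: float  # vOTUs per read over the last four points
    prediction: float  # expected new vOTUs per additional 10^6 reads


def fit_rarefaction_tail(points: Sequence[tuple[int, float]]) -> tuple[float, float]:
    """Least-squares slope over the last four points and the implied vOTU
    gain per additional million reads."""
    if len(points) < 4:
        raise ValueError("need at least 4 subsample depths")
    tail = points[-4:]
    x = np.array([p[0] for p in tail], dtype=float)
    y = np.array([p[1] for p in tail], dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    return slope, slope * 1e6


def rarefy(
    records: Sequence[AlignmentRecord],
    refs: Sequence[Contig],
    depths: Sequence[int],
    seed: int,
    min_breadth: float = 0.70,
    min_identity: float = 0.95,
    min_read_frac: float = 0.90,
) -> RarefactionCurve:
    """Rarefaction by seeded read subsampling without replacement.

    ``records`` are per-read alignments (one record per read); at each depth
    a random subset of reads is drawn, alignments are filtered, and a vOTU
    counts as detected when its breadth reaches ``min_breadth``.
    """
    depths = sorted(depths)
    if len(depths) < 4:
        raise ValueError("need at least 4 subsample depths")
    n_reads = len(records)
    if depths[-1] > n_reads:
        raise ValueError("subsample depth exceeds library size")
    rng = np.random.default_rng(seed)
    by_ref = {c.id: c for c in refs}
    points: list[tuple[int, int]] = []
    for d in depths:
        idx = rng.choice(n_reads, size=d, replace=False)
        sub = [records[i] for i in idx]
        kept = filter_alignments(sub, min_identity, min_read_frac)
        grouped: dict[str, list[AlignmentRecord]] = {}
        for r in kept:
            grouped.setdefault(r.contig_id, []).append(r)
        detected = 0
        for cid, recs in grouped.items():
            prof = depth_profile(recs, by_ref[cid])
            if breadth(prof) >= min_breadth:
                detected += 1
        points.append((d, detected))
    slope, prediction = fit_rarefaction_tail(points)
    return RarefactionCurve(points, slope, prediction)


def call_active(
    transcript_records: Sequence[AlignmentRecord],
    votus: Sequence[Contig],
    genes: Sequence[GeneRecord] = (),
    min_identity: float = 0.90,
    min_read_frac: float = 0.90,
    min_breadth: float = 0.50,
) -> pd.DataFrame:
    """Metatranscriptomic activity calls per vOTU.

    A vOTU is putatively active when filtered transcript reads cover at
    least ``min_breadth`` of its genome. Returns per-vOTU breadth, the
    active flag, and (for active vOTUs with gene annotations) mean
    transcript depth per gene as a nested frame in ``gene_depths``.
    """
    kept = filter_alignments(transcript_records, min_identity, min_read_frac)
    grouped: dict[str, list[AlignmentRecord]] = {}
    for r in kept:
        grouped.setdefault(r.contig_id, []).append(r)
    rows = []
    for contig in votus:
        recs = grouped.get(contig.id, [])
        prof = depth_profile(recs, contig) if recs else DepthProfile(
            contig.id, np.zeros(len(contig), dtype=np.int64)
        )
        b = breadth(prof)
        active = b >= min_breadth
        gene_depths = {}
        if active:
            for g in genes:
                if g.contig_id == contig.id:
                    gene_depths[g.gene_id] = float(
                        prof.depth[g.start : g.end].mean()
                    )
        rows.append(
            {
                "votu": contig.id,
                "transcript_breadth": b,
                "active": active,
                "gene_depths": gene_depths,
            }
        )
    return pd.DataFrame(rows)
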