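"""Viral-contig classification, species-level vOTU clustering, and N50.

Classification combines three detector score columns (VirSorter category,
DeepVirFinder score + p, MARVEL probability) under a four-criterion OR rule.
Clustering is greedy and representative-anchored: contigs sorted by length
descending, each joining the first cluster whose representative shares
>= 95% nucleotide identity over >= 80% of the shorter sequence, otherwise
founding its own cluster — so the longest member is always the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import Contig


@dataclass
class DetectorScores:
    """Scores from the three virus detectors for one contig; absent fields
    simply fail their criteria."""

    contig_id: str
    vs_category: Optional[int] = None
    dvf_score: Optional[float] = None
    dvf_p: Optional[float] = None
    marvel_prob: Optional[float] = None

    def __post_init__(self) -> None:
        if all(
            v is None
            for v in (self.vs_category, self.dvf_score, self.dvf_p, self.marvel_prob)
        ):
            raise ValueError(f"{self.contig_id}: no detector fields present")
        if self.dvf_score is not None and not 0 <= self.dvf_score <= 1:
            raise ValueError("dvf_score outside [0, 1]")
        if self.marvel_prob is not None and not 0 <= self.marvel_prob <= 100:
            raise ValueError("marvel_prob outside [0, 100]")


@dataclass
class VOTUCluster:
    representative_id: str
    member_ids: list[str]
    rep_length: int


def classify_viral(scores: DetectorScores) -> tuple[bool, list[int]]:
    """Apply the four-criterion viral classification rule.

    A contig is viral if it meets any of:
      1. VirSorter category in {1, 2, 4, 5};
      2. DeepVirFinder score >= 0.9 and p < 0.05;
      3. MARVEL probability >= 90;
      4. DeepVirFinder score >= 0.7 and p < 0.05 and MARVEL >= 70.

    Returns (is_viral, list of satisfied criterion numbers).
    """
    hit: list[int] = []
    if scores.vs_category in (1, 2, 4, 5):
        hit.append(1)
    dvf_ok = scores.dvf_score is not None and scores.dvf_p is not None and scores.dvf_p < 0.05
    if dvf_ok and scores.dvf_score >= 0.9:
        hit.append(2)
    if scores.marvel_prob is not None and scores.marvel_prob >= 90:
        hit.append(3)
    if dvf_ok and scores.dvf_score >= 0.7 and scores.marvel_prob is not None and scores.marvel_prob >= 70:
        hit.append(4)
    return bool(hit), hit


def read_scores_tsv(path: str | Path) -> list[DetectorScores]:
    """Read a detector score table (empty cell = absent field)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    out = []
    for row in df.itertuples(index=False):
        def _get(name, cast):
            v = getattr(row, name, None)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else cast(v)

        out.append(
            DetectorScores(
                contig_id=row.contig_id,
                vs_category=_get("vs_category", int),
                dvf_score=_get("dvf_score", float),
                dvf_p=_get("dvf_p", float),
                marvel_prob=_get("marvel_prob", float),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pairwise ANI


def pairwise_ani(
    a: Contig | str, b: Contig | str, k: int = 15, min_block: int = 100
) -> tuple[float, float]:
    """K-mer-anchored ANI and aligned fraction between two sequences.

    Shared exact k-mers are grouped by diagonal; each diagonal's anchors are
    merged into one ungapped block spanning first to last anchor, blocks
    shorter than ``min_block`` are dropped, and overlaps between blocks are
    trimmed so no position is counted twice. Returns

    * ``ani``: length-weighted mean percent identity over retained blocks,
    * ``af_shorter``: percent of the shorter sequence covered by blocks.

    Symmetric in its arguments. Suited to the substitution-dominated
    divergence this rule is applied to; an indel shifts the diagonal and
    simply starts a new block.
    """
    sa = a.seq if isinstance(a, Contig) else a
    sb = b.seq if isinstance(b, Contig) else b
    if not sa or not sb:
        raise ValueError("empty sequence")
    # index the shorter sequence for memory locality; result is symmetric
    swap = len(sa) > len(sb)
    if swap:
        sa, sb = sb, sa
    short_len = len(sa)
    index: dict[str, list[int]] = {}
    for i in range(len(sa) - k + 1):
        index.setdefault(sa[i : i + k], []).append(i)
    # anchors grouped by diagonal (pos_a - pos_b)
    diags: dict[int, list[tuple[int, int]]] = {}
    for j in range(len(sb) - k + 1):
        kmer = sb[j : j + k]
        hits = index.get(kmer)
        if hits:
            for i in hits:
                diags.setdefault(i - j, []).append((i, j))
    aa = np.frombuffer(sa.encode(), dtype=np.uint8)
    bb = np.frombuffer(sb.encode(), dtype=np.uint8)
    blocks: list[tuple[int, int, int]] = []  # (start_a, end_a, matches)
    for d, anchors in diags.items():
        ia = min(p[0] for p in anchors)
        ea = max(p[0] for p in anchors) + k
        if ea - ia < min_block:
            continue
        seg_a = aa[ia:ea]
        seg_b = bb[ia - d : ea - d]
        matches = int(np.count_nonzero(seg_a == seg_b))
        blocks.append((ia, ea, matches))
    if not blocks:
        return 0.0, 0.0
    # greedy overlap removal on the shorter sequence, longest blocks first
    blocks.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    covered = np.zeros(short_len, dtype=bool)
    tot_cols = 0
    tot_match = 0
    for ia, ea, matches in blocks:
        seg = covered[ia:ea]
        new = int(np.count_nonzero(~seg))
        if new < (ea - ia):
            # trim proportionally: keep only block mass on uncovered columns
            matches = int(round(matches * new / (ea - ia)))
        if new == 0:
            continue
        tot_cols += new
        tot_match += matches
        covered[ia:ea] = True
    if tot_cols == 0:
        return 0.0, 0.0
    ani = 100.0 * tot_match / tot_cols
    af = 100.0 * tot_cols / short_len
    return ani, af


def oracle_ani(a: Contig | str, b: Contig | str) -> tuple[float, float]:
    """Exhaustive local-DP oracle for the same (ani, af_shorter) quantities.

    Best local alignment via Biopython's PairwiseAligner (match 1, mismatch
    -1, gap -2); identity and aligned columns are read off the optimal path.
    Independent of the k-mer route; intended for small test fixtures.
    """
    from Bio import Align

    sa = a.seq if isinstance(a, Contig) else a
    sb = b.seq if isinstance(b, Contig) else b
    if len(sa) > len(sb):
        sa, sb = sb, sa
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(sa, sb)[0]
    matches = 0
    cols = 0
    short_cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        seg_a = sa[a0:a1]
        seg_b = sb[b0:b1]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        cols += a1 - a0
        short_cols += a1 - a0
    if cols == 0:
        return 0.0, 0.0
    return 100.0 * matches / cols, 100.0 * short_cols / len(sa)


def cluster_votus(
    contigs: Sequence[Contig],
    min_ani: float = 95.0,
    min_af: float = 80.0,
    ani_fn: Callable[[Contig, Contig], tuple[float, float]] = pairwise_ani,
) -> list[VOTUCluster]:
    """Greedy species-level clustering of viral contigs.

    Contigs are processed longest-first (ties broken by id); each joins the
    first existing cluster whose representative meets both thresholds, else
    it founds a new cluster. The founder — the longest member — is the seed.
    """
    if not contigs:
        raise ValueError("no contigs to cluster")
    ordered = sorted(contigs, key=lambda c: (-len(c), c.id))
    clusters: list[VOTUCluster] = []
    reps: list[Contig] = []
    for c in ordered:
        placed = False
        for cl, rep in zip(clusters, reps):
            ani, af = ani_fn(c, rep)
            if ani >= min_ani and af >= min_af:
                cl.member_ids.append(c.id)
                placed = True
                break
        if not placed:
            clusters.append(VOTUCluster(c.id, [c.id], len(c)))
            reps.append(c)
    return clusters


def screen_contaminants(
    contigs: Sequence[Contig],
    contaminants: Sequence[Contig],
    min_ani: float = 95.0,
    min_af: float = 80.0,
) -> tuple[list[Contig], list[str]]:
    """Drop contigs matching a lab-contaminant exclusion list under the same
    ANI/AF rule used for clustering. Returns (kept, dropped ids)."""
    kept: list[Contig] = []
    dropped: list[str] = []
    for c in contigs:
        hit = any(
            ani >= min_ani and af >= min_af
            for ani, af in (pairwise_ani(c, lab) for lab in contaminants)
        )
        if hit:
            dropped.append(c.id)
        else:
            kept.append(c)
    return kept, dropped


def n50(lengths: Iterable[int]) -> int:
    """Smallest length among the largest contigs whose cumulative sum first
    reaches half the assembly total."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("empty length list")
    half = sum(ls) / 2.0
    acc = 0
    for L in ls:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


def clusters_to_frame(clusters: Sequence[VOTUCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "votu_id": [f"vOTU{i + 1}" for i in range(len(clusters))],
            "representative": [c.representative_id for c in clusters],
            "members": [",".join(c.member_ids) for c in clusters],
            "rep_length": [c.rep_length for c in clusters],
        }
    )
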