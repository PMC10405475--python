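"""Alignment filtering, per-base depth, allele counts, normalized abundance.

The read filters mirror the viromic mapping convention: a read is retained
iff its alignment identity (1 - NM / alignment columns) and its aligned
read fraction both clear the thresholds — 95% identity and 90% of the read
for abundance profiling by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, Contig

_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class DepthProfile:
    contig_id: str
    depth: np.ndarray  # int per position

    @property
    def mean(self) -> float:
        return float(self.depth.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.depth))


@dataclass
class SiteCounts:
    """Per-position A/C/G/T observation counts for one contig."""

    contig_id: str
    counts: np.ndarray  # shape (L, 4)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def identity(rec: AlignmentRecord) -> float:
    """Edit-distance identity: 1 - NM / alignment columns (indels counted)."""
    if rec.n_mismatch < 0:
        raise ValueError(f"negative NM on {rec.read_id!r}")
    cols = rec.aligned_columns
    return 1.0 - rec.n_mismatch / cols if cols else 0.0


def read_fraction(rec: AlignmentRecord) -> float:
    """Fraction of the read inside aligned columns (clips excluded)."""
    return rec.query_aligned / rec.read_len if rec.read_len else 0.0


def filter_alignments(
    records: Iterable[AlignmentRecord],
    min_identity: float = 0.95,
    min_read_frac: float = 0.90,
) -> list[AlignmentRecord]:
    """Retain mapped records meeting both identity and read-fraction cutoffs.

    Retention is per-record and order-independent.
    """
    return [
        r
        for r in records
        if r.mapped
        and identity(r) >= min_identity
        and read_fraction(r) >= min_read_frac
    ]


def depth_profile(records: Iterable[AlignmentRecord], contig: Contig) -> DepthProfile:
    """Per-base depth: every reference-consumed position counts once per
    read; deletions within a read still consume (and cover) reference."""
    L = len(contig)
    diff = np.zeros(L + 1, dtype=np.int64)
    for rec in records:
        if rec.contig_id != contig.id:
            raise ValueError(f"record {rec.read_id!r} not on contig {contig.id!r}")
        pos = rec.start
        for op, n in rec.cigar:
            if op in "MDN=X":
                if pos + n > L:
                    raise ValueError(
                        f"record {rec.read_id!r} exceeds bounds of {contig.id!r}"
                    )
                diff[pos] += 1
                diff[pos + n] -= 1
                pos += n
    return DepthProfile(contig.id, np.cumsum(diff[:-1]))


def breadth(profile: DepthProfile, min_depth: int = 1) -> float:
    """Fraction of positions covered at >= min_depth."""
    return float(np.count_nonzero(profile.depth >= min_depth)) / len(profile.depth)


def allele_counts(records: Iterable[AlignmentRecord], contig: Contig) -> SiteCounts:
    """Pileup allele counts from aligned (ref+query consuming) columns.

    Read bases outside ACGT are dropped; positions where the reference is N
    are zeroed (undefined reference allele).
    """
    L = len(contig)
    counts = np.zeros((L, 4), dtype=np.int64)
    pos_chunks: list[np.ndarray] = []
    base_chunks: list[np.ndarray] = []
    for rec in records:
        if rec.contig_id != contig.id:
            raise ValueError(f"record {rec.read_id!r} not on contig {contig.id!r}")
        if not rec.seq:
            raise ValueError(f"record {rec.read_id!r} carries no sequence")
        seq = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
        rpos = rec.start
        qpos = 0
        for op, n in rec.cigar:
            if op in "M=X":
                pos_chunks.append(np.arange(rpos, rpos + n))
                base_chunks.append(seq[qpos : qpos + n])
                rpos += n
                qpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                rpos += n
    if pos_chunks:
        pos = np.concatenate(pos_chunks)
        codes = _BASE_INDEX[np.concatenate(base_chunks)]
        keep = codes >= 0
        np.add.at(counts, (pos[keep], codes[keep].astype(np.int64)), 1)
    ref = np.frombuffer(contig.seq.encode(), dtype=np.uint8)
    counts[ref == ord("N")] = 0
    return SiteCounts(contig.id, counts)


def abundance_table(
    profiles_by_sample: Mapping[str, Mapping[str, DepthProfile]],
    library_bases: Mapping[str, int],
) -> pd.DataFrame:
    """vOTU x sample table of coverage per gigabase of virome.

    Entry = mean depth of the vOTU representative x 10^9 / library bases.
    """
    samples = list(profiles_by_sample)
    votus = sorted({v for s in samples for v in profiles_by_sample[s]})
    data = np.zeros((len(votus), len(samples)))
    for j, s in enumerate(samples):
        lib = library_bases[s]
        if lib <= 0:
            raise ValueError(f"library size for {s!r} must be > 0")
        for i, v in enumerate(votus):
            prof = profiles_by_sample[s].get(v)
            if prof is not None:
                data[i, j] = prof.mean * 1e9 / lib
    return pd.DataFrame(data, index=votus, columns=samples)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Within-sample relative abundances (columns sum to 1 where nonzero)."""
    sums = table.sum(axis=0)
    return table.div(sums.where(sums > 0, other=np.nan), axis=1).fillna(0.0)
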