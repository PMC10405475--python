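"""Hypervariable-region (genomic-island) detection from per-base depth.

A contig is eligible when its median depth is at least ``min_median`` (5x by
default); a position is "low" when its depth is at most ``frac`` (20%) of
that median; an HVR is a maximal run of consecutive low positions at least
``min_len`` (500 bp) long. Because the rule is a ratio against the contig's
own median, uniformly rescaling depth leaves the calls unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage_profiles import DepthProfile


@dataclass
class HVRInterval:
    contig_id: str
    start: int  # 0-based half-open
    end: int
    island_mean_depth: float
    contig_median_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_hvrs(
    profile: DepthProfile,
    frac: float = 0.20,
    min_len: int = 500,
    min_median: float = 5.0,
    max_gap: int = 0,
) -> list[HVRInterval]:
    """Detect HVRs on one contig; returns disjoint intervals left to right.

    ``max_gap`` > 0 allows bridging runs separated by at most that many
    non-low positions (default 0: strict runs).
    """
    depth = np.asarray(profile.depth)
    med = float(np.median(depth))
    if med < min_median:
        return []
    low = depth <= frac * med
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(low)))
    if max_gap > 0 and runs:
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] <= max_gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        runs = merged
    return [
        HVRInterval(
            profile.contig_id, s, e, float(depth[s:e].mean()), med
        )
        for s, e in runs
        if e - s >= min_len
    ]


def hvr_summary(
    hvrs_by_label: Mapping[str, Sequence[HVRInterval]],
    contig_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-label HVR counts, total lengths, and HVR density (HVR bp per
    contig bp, when contig lengths are supplied)."""
    rows = []
    for label, hvrs in hvrs_by_label.items():
        total = sum(h.length for h in hvrs)
        density = np.nan
        if contig_lengths:
            contig_bp = sum(
                contig_lengths[c] for c in {h.contig_id for h in hvrs}
            )
            density = total / contig_bp if contig_bp else np.nan
        rows.append(
            {
                "label": label,
                "n_hvrs": len(hvrs),
                "total_hvr_bp": total,
                "hvr_density": density,
            }
        )
    return pd.DataFrame(rows)


def hvrs_to_bed(hvrs: Iterable[HVRInterval]) -> str:
    """BED (0-based half-open) text for detected intervals."""
    lines = [
        f"{h.contig_id}\t{h.start}\t{h.end}\thvr\t{h.island_mean_depth:.2f}"
        for h in hvrs
    ]
    return "\n".join(lines) + ("\n" if lines else "")
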