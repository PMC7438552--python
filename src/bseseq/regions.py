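"""Candidate-region calling from windowed scores.

Turns the per-window varBScore track into discrete candidate regions: windows
scoring at or above a high quantile of the positive scores are selected, and
selected windows on the same chromosome within a merge gap are fused into one
region.  The threshold is a quantile rather than an absolute score because
the varBScore scale depends on the pseudocount c; the default merge gap of
5 Mb reflects the Mb-scale linkage blocks of a large plant genome.  Ties at
the threshold are included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import BulkVariant
from .varbscore import WindowScore

__all__ = ["CandidateRegion", "call_regions", "rank_candidates", "write_region_bed"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateRegion:
    """A merged run of high-scoring windows (1-based inclusive coordinates)."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_score: float
    n_windows: int
    n_snps: int

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp


def call_regions(
    window_scores: Sequence[WindowScore],
    threshold_quantile: float = 0.999,
    merge_gap_bp: int = 5_000_000,
) -> list[CandidateRegion]:
    """Select windows at/above the score quantile and merge nearby ones.

    The quantile is taken over strictly positive varBScores only; if there are
    none, an empty list is returned with a warning.  Returned regions never
    overlap and are ranked by peak score, descending.
    """
    positive = [w.varbscore for w in window_scores if w.varbscore > 0]
    if not positive:
        log.warning("no windows with a positive varBScore; no regions called")
        return []
    # 'lower' makes the threshold an attained score, so tie inclusion is meaningful
    threshold = float(np.quantile(positive, threshold_quantile, method="lower"))
    selected = sorted(
        (w for w in window_scores if w.varbscore >= threshold),
        key=lambda w: (w.chrom, w.start_pos),
    )

    regions: list[CandidateRegion] = []
    cluster: list[WindowScore] = []

    def flush() -> None:
        if not cluster:
            return
        ranks_span = max(w.rank_end for w in cluster) - min(w.rank_start for w in cluster) + 1
        regions.append(
            CandidateRegion(
                chrom=cluster[0].chrom,
                start_bp=min(w.start_pos for w in cluster),
                end_bp=max(w.end_pos for w in cluster),
                peak_score=max(w.varbscore for w in cluster),
                n_windows=len(cluster),
                n_snps=ranks_span,
            )
        )

    for w in selected:
        if cluster and (
            w.chrom != cluster[-1].chrom
            or w.start_pos - max(c.end_pos for c in cluster) > merge_gap_bp
        ):
            flush()
            cluster = []
        cluster.append(w)
    flush()

    regions.sort(key=lambda r: r.peak_score, reverse=True)
    return regions


def rank_candidates(
    regions: Sequence[CandidateRegion],
    cascade_survivors: Sequence[BulkVariant],
) -> tuple[list[tuple[BulkVariant, CandidateRegion]], list[BulkVariant]]:
    """Rank cascade survivors inside called regions.

    Survivors falling inside a region are ordered by the enclosing region's
    peak score (descending), then by per-SNP |M − W| (descending); survivors
    outside all regions are returned separately as a remainder list.
    """
    ranked: list[tuple[BulkVariant, CandidateRegion]] = []
    remainder: list[BulkVariant] = []
    for v in cascade_survivors:
        hit = next((r for r in regions if r.contains(v.chrom, v.pos)), None)
        if hit is None:
            remainder.append(v)
        else:
            ranked.append((v, hit))

    def delta(v: BulkVariant) -> float:
        m, w = v.mutant.alt_frequency, v.wild.alt_frequency
        if m is None or w is None:
            return 0.0
        return abs(m - w)

    ranked.sort(key=lambda vr: (-vr[1].peak_score, -delta(vr[0])))
    return ranked, remainder


def write_region_bed(regions: Sequence[CandidateRegion], path: str | Path) -> Path:
    """Write regions as BED (0-based half-open), one line per region."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start_bp - 1 for r in regions],
            "end": [r.end_bp for r in regions],
            "name": [f"region_{i + 1}" for i in range(len(regions))],
            "score": [r.peak_score for r in regions],
        }
    )
    frame.to_csv(path, sep="\t", index=False, header=False)
    return path
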