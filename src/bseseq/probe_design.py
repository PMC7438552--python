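"""Capture-probe repetitiveness scoring via a genome 15-mer histogram.

Hybridisation-capture probes placed in repetitive sequence pull down reads
from many loci at once, so probe design screens candidates against genome
k-mer frequencies: a histogram of all 15-mers in the reference is built, each
candidate probe is scored from the counts of its constituent 15-mers, and
probes scoring above 100 are rejected as repetitive.  k-mers are counted in
canonical (strand-merged) form because capture hybridisation is
strand-agnostic.

The probe score is the MEAN of the constituent canonical k-mer counts by
default (so a fully unique probe scores exactly 1.0); a ``max`` mode is also
offered since the aggregation rule is a design choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ProbeCandidate",
    "reverse_complement",
    "canonical_kmer",
    "build_kmer_histogram",
    "score_probe",
    "tile_targets",
    "read_bed",
    "summarize_targets",
]

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = frozenset("ACGT")

DEFAULT_K = 15
DEFAULT_PROBE_LENGTH = 120
DEFAULT_SCORE_THRESHOLD = 100.0


@dataclass(frozen=True)
class ProbeCandidate:
    """One candidate probe tile. ``start`` is 0-based on the chromosome."""

    chrom: str
    start: int
    length: int
    sequence: str
    kmer_score: float | None
    status: str  # retained | rejected_repetitive | rejected_gap

    @property
    def end(self) -> int:
        return self.start + self.length


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _sequences(genome) -> Iterable[tuple[str, str]]:
    """Iterate (name, sequence) over a FASTA path, pyfaidx.Fasta, or mapping."""
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fasta = Fasta(str(genome))
        for name in fasta.keys():
            yield name, str(fasta[name][:])
    elif isinstance(genome, Mapping):
        yield from genome.items()
    else:  # pyfaidx.Fasta or similar
        for name in genome.keys():
            yield name, str(genome[name][:])


def build_kmer_histogram(genome, k: int = DEFAULT_K) -> dict[str, int]:
    """Count every canonical k-mer in the genome.

    ``genome`` may be a FASTA path, a pyfaidx.Fasta, or a {name: sequence}
    mapping.  k-mers containing any non-ACGT character (Ns, gaps) are
    skipped; sequences shorter than k contribute nothing (with a warning).
    """
    counts: dict[str, int] = {}
    for name, seq in _sequences(genome):
        seq = seq.upper()
        if len(seq) < k:
            log.warning("sequence %s is shorter than k=%d, skipped", name, k)
            continue
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if not _VALID.issuperset(kmer):
                continue
            key = canonical_kmer(kmer)
            counts[key] = counts.get(key, 0) + 1
    return counts


def score_probe(
    sequence: str, histogram: Mapping[str, int], k: int = DEFAULT_K, mode: str = "mean"
) -> float:
    """Repetitiveness score of one probe from the genome k-mer histogram.

    Mean (default) or max of the histogram counts of the probe's len−k+1
    constituent canonical k-mers; k-mers absent from the histogram count 0.
    Raises on probes containing non-ACGT characters or shorter than k.
    """
    seq = sequence.upper()
    if len(seq) < k:
        raise ValueError(f"probe length {len(seq)} is shorter than k={k}")
    if not _VALID.issuperset(seq):
        raise ValueError("probe contains non-ACGT characters; score undefined")
    counts = [
        histogram.get(canonical_kmer(seq[i : i + k]), 0)
        for i in range(len(seq) - k + 1)
    ]
    if mode == "mean":
        return sum(counts) / len(counts)
    if mode == "max":
        return float(max(counts))
    raise ValueError(f"unknown scoring mode {mode!r} (use 'mean' or 'max')")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals (0-based half-open) as (chrom, start, end) tuples."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return intervals


def tile_targets(
    targets: Sequence[tuple[str, int, int]] | str | Path,
    genome,
    histogram: Mapping[str, int] | None = None,
    probe_length: int = DEFAULT_PROBE_LENGTH,
    stride: int | None = None,
    k: int = DEFAULT_K,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    mode: str = "mean",
) -> tuple[list[ProbeCandidate], pd.DataFrame]:
    """Tile target intervals with probes, score each, and summarise coverage.

    ``targets`` is a BED path or a list of (chrom, start, end) 0-based
    half-open intervals.  Probes are placed every ``stride`` bp (default:
    probe_length, i.e. non-overlapping), with a final right-aligned probe so
    the tail of each target is tiled.  A probe containing N is
    ``rejected_gap``; a probe scoring strictly above the threshold is
    ``rejected_repetitive``; the rest are retained.

    The per-target summary partitions every target base exactly once:
    covered (under ≥1 retained probe), lost to gaps (uncovered N bases), or
    lost to repeats (uncovered non-N bases).
    """
    if isinstance(targets, (str, Path)):
        targets = read_bed(targets)
    seqs = dict(_sequences(genome))
    if histogram is None:
        histogram = build_kmer_histogram(seqs, k=k)
    stride = stride or probe_length

    probes: list[ProbeCandidate] = []
    rows = []
    for chrom, start, end in targets:
        if chrom not in seqs or start < 0 or end > len(seqs[chrom]) or start >= end:
            log.warning("target %s:%d-%d out of genome bounds, skipped", chrom, start, end)
            continue
        target_seq = seqs[chrom][start:end].upper()
        tlen = end - start
        plen = min(probe_length, tlen)
        covered = [False] * tlen
        target_probes: list[ProbeCandidate] = []
        if plen >= k:
            offsets = list(range(0, tlen - plen + 1, stride))
            if offsets[-1] != tlen - plen:
                offsets.append(tlen - plen)  # right-aligned tail probe
            for off in offsets:
                seq = target_seq[off : off + plen]
                if not _VALID.issuperset(seq):
                    p = ProbeCandidate(chrom, start + off, plen, seq, None, "rejected_gap")
                else:
                    score = score_probe(seq, histogram, k=k, mode=mode)
                    status = "rejected_repetitive" if score > score_threshold else "retained"
                    p = ProbeCandidate(chrom, start + off, plen, seq, score, status)
                    if status == "retained":
                        for j in range(off, off + plen):
                            covered[j] = True
                target_probes.append(p)
        else:
            log.warning("target %s:%d-%d shorter than k=%d, not tiled", chrom, start, end, k)
        probes.extend(target_probes)

        n_cov = sum(covered)
        n_gap = sum(1 for j in range(tlen) if not covered[j] and target_seq[j] == "N")
        n_rep = tlen - n_cov - n_gap
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "target_bases": tlen,
                "bases_covered": n_cov,
                "pct_covered": 100.0 * n_cov / tlen,
                "bases_lost_gaps": n_gap,
                "bases_lost_repeats": n_rep,
                "n_probes_retained": sum(1 for p in target_probes if p.status == "retained"),
                "n_probes_rejected": sum(1 for p in target_probes if p.status != "retained"),
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "target_bases", "bases_covered", "pct_covered",
            "bases_lost_gaps", "bases_lost_repeats", "n_probes_retained", "n_probes_rejected",
        ],
    )
    return probes, summary


def summarize_targets(summary: pd.DataFrame) -> dict[str, float]:
    """Panel-level totals in the shape of a capture-design summary table."""
    total = int(summary["target_bases"].sum()) if len(summary) else 0
    covered = int(summary["bases_covered"].sum()) if len(summary) else 0
    gaps = int(summary["bases_lost_gaps"].sum()) if len(summary) else 0
    reps = int(summary["bases_lost_repeats"].sum()) if len(summary) else 0
    return {
        "n_regions": int(len(summary)),
        "target_bases": total,
        "target_bases_covered": covered,
        "pct_target_bases_covered": 100.0 * covered / total if total else 0.0,
        "bases_lost_gaps": gaps,
        "bases_lost_repeats": reps,
    }
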