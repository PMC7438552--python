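"""The varBScore sliding-window statistic and the ΔSNP-index comparison.

Bulked-segregant mapping looks for the genomic region where the two bulks'
allele frequencies behave as the cross design predicts.  For an F2 population
segregating one recessive causal mutation, phenotype selection fixes the
mutant bulk at alternate-allele frequency m̄ = 1 at the causal locus, while
the wild bulk (a 1:2 mix of homozygous wild-type and heterozygotes) sits at
w̄ = 1/3.  Markers tightly linked to the causal site approach those same
expectations; unlinked markers fluctuate around 1/2.

varBScore scores a window of n SNPs by how little each pool deviates from its
expectation.  With M_j and W_j the observed mutant/wild-bulk frequencies at
SNP j of the window,

    SD_M = sqrt( Σ_j (M_j − m̄)² / (n − 1) )      (likewise SD_W with w̄)
    varBScore = −log10(SD_M + c) × −log10(SD_W + c)

where c is a small pseudocount that caps the score at (−log10 c)² when both
pools sit exactly at expectation.  Because the score requires BOTH pools to
match their expectations simultaneously, random frequency swings in a single
pool — the main source of false peaks in the plain ΔSNP-index — do not
produce high scores.

Windows are defined in SNP rank (a fixed number of SNPs, default 20, advanced
by a fixed step, default 5), never in physical distance, and never span
chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_io import BulkVariant

__all__ = [
    "PopulationDesign",
    "ScoreConfig",
    "WindowScore",
    "expected_frequencies",
    "df_filter",
    "sd_from_expectation",
    "varbscore_window",
    "snp_index_window",
    "sliding_windows",
    "score_variants",
    "windows_to_frame",
    "write_window_table",
    "plot_windows",
]

# design -> (expected alt AF in mutant bulk m̄, expected alt AF in wild bulk w̄)
_DESIGNS: dict[str, tuple[float, float]] = {
    "f2_recessive": (1.0, 1.0 / 3.0),
    "f2_dominant": (2.0 / 3.0, 0.0),
    "backcross_recessive": (1.0, 1.0 / 3.0),
    "ril": (1.0, 0.0),
    "dh": (1.0, 0.0),
}


@dataclass(frozen=True)
class PopulationDesign:
    """Expected bulk allele frequencies implied by a cross design.

    ``expected_af_mutant_bulk`` (m̄) and ``expected_af_wild_bulk`` (w̄) are the
    alternate-allele frequencies the two bulks would show at the causal locus
    under perfect phenotype selection.
    """

    design_name: str
    expected_af_mutant_bulk: float
    expected_af_wild_bulk: float

    def __post_init__(self) -> None:
        for x in (self.expected_af_mutant_bulk, self.expected_af_wild_bulk):
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"expected allele frequencies must be in [0,1], got {x}")

    def swapped(self) -> "PopulationDesign":
        """The same design with the two bulks' roles exchanged."""
        return PopulationDesign(
            self.design_name + "_swapped",
            self.expected_af_wild_bulk,
            self.expected_af_mutant_bulk,
        )


def expected_frequencies(design_name: str) -> PopulationDesign:
    """Expected (m̄, w̄) for a named cross design.

    f2_recessive: mutant bulk is all aa (m̄ = 1); wild bulk is AA:Aa = 1:2
    (w̄ = 1/3).  f2_dominant mirrors this with the bulks swapped (the
    dominant-phenotype bulk is Aa:aa = 2:1, alt AF 2/3; the recessive bulk is
    AA only).  RIL and DH populations have no heterozygotes, so (1, 0).
    A backcross followed by selfing (BCnF2) segregates the same three genotype
    classes as an F2 and shares its expectations.
    """
    try:
        m_bar, w_bar = _DESIGNS[design_name]
    except KeyError:
        raise ValueError(
            f"unknown design {design_name!r}; supported designs: {sorted(_DESIGNS)}"
        ) from None
    return PopulationDesign(design_name, m_bar, w_bar)


@dataclass(frozen=True)
class ScoreConfig:
    """Windowing and scoring parameters.

    window_n: SNPs per window (default 20); step: SNPs advanced per window
    (default 5); c: pseudocount inside the logs, from the ladder
    0.01 / 0.001 / 0.0001 (default 0.01, capping the score at 4);
    df_threshold: minimum |M − W| for a SNP to enter windows (default 0.3 —
    the causal geometry gives |1 − 1/3| = 2/3, so 0.3 keeps tightly linked
    SNPs while removing symmetric noise); clamp_negative: floor each log term
    at 0 so that windows far from BOTH expectations cannot multiply two
    negative terms into a spurious positive score.
    """

    window_n: int = 20
    step: int = 5
    c: float = 0.01
    df_threshold: float = 0.3
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.window_n < 2:
            raise ValueError("window_n must be >= 2")
        if not 1 <= self.step <= self.window_n:
            raise ValueError("step must satisfy 1 <= step <= window_n")
        if not 0.0 < self.c < 1.0:
            raise ValueError("c must be in (0, 1)")
        if not 0.0 <= self.df_threshold <= 1.0:
            raise ValueError("df_threshold must be in [0, 1]")


@dataclass(frozen=True)
class WindowScore:
    """One scored window of consecutive SNPs on one chromosome."""

    chrom: str
    start_pos: int
    end_pos: int
    n_snps: int
    sd_mutant: float
    sd_wild: float
    varbscore: float
    mean_delta_snp_index: float
    rank_start: int = 0  # 0-based rank of the first SNP within its chromosome's SNP list
    rank_end: int = 0

    @property
    def mid_pos(self) -> int:
        return (self.start_pos + self.end_pos) // 2


def df_filter(variants: Sequence[BulkVariant], df_threshold: float) -> list[BulkVariant]:
    """Keep SNPs whose pools differ: |M − W| strictly greater than the threshold.

    Requires the allele frequency to be defined (nonzero coverage) in both
    pools; sites where it is not are dropped.
    """
    out = []
    for v in variants:
        m = v.mutant.alt_frequency
        w = v.wild.alt_frequency
        if m is None or w is None:
            continue
        if abs(m - w) > df_threshold:
            out.append(v)
    return out


def sd_from_expectation(observed_afs: Sequence[float], expected: float) -> float:
    """Root-mean-square deviation of observed frequencies from the EXPECTED
    frequency, with an n−1 denominator:  sqrt(Σ(x_j − expected)² / (n − 1)).

    Deviation is measured from the design expectation, not the window mean, so
    a window whose pool sits uniformly at the wrong frequency still registers
    a large deviation.  Can exceed 1 (e.g. all-zero observations against an
    expectation of 1 give sqrt(n/(n−1))).
    """
    x = np.asarray(observed_afs, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 observations for the n-1 denominator, got {n}")
    return float(np.sqrt(np.sum((x - expected) ** 2) / (n - 1)))


def varbscore_window(
    mutant_afs: Sequence[float],
    wild_afs: Sequence[float],
    design: PopulationDesign,
    c: float = 0.01,
    clamp_negative: bool = True,
) -> float:
    """varBScore of one window: product of per-pool −log10(SD + c) terms."""
    if len(mutant_afs) != len(wild_afs):
        raise ValueError(
            f"window length mismatch: {len(mutant_afs)} mutant vs {len(wild_afs)} wild AFs"
        )
    sd_m = sd_from_expectation(mutant_afs, design.expected_af_mutant_bulk)
    sd_w = sd_from_expectation(wild_afs, design.expected_af_wild_bulk)
    term_m = -math.log10(sd_m + c)
    term_w = -math.log10(sd_w + c)
    if clamp_negative:
        term_m = max(term_m, 0.0)
        term_w = max(term_w, 0.0)
    return term_m * term_w


def snp_index_window(mutant_afs: Sequence[float], wild_afs: Sequence[float]) -> float:
    """Mean ΔSNP-index of the window: mean over SNPs of (M_j − W_j), in [−1, 1]."""
    if len(mutant_afs) != len(wild_afs):
        raise ValueError(
            f"window length mismatch: {len(mutant_afs)} mutant vs {len(wild_afs)} wild AFs"
        )
    if len(mutant_afs) == 0:
        raise ValueError("empty window")
    m = np.asarray(mutant_afs, dtype=float)
    w = np.asarray(wild_afs, dtype=float)
    return float(np.mean(m - w))


def sliding_windows(
    variants: Sequence[BulkVariant],
    cfg: ScoreConfig,
    design: PopulationDesign,
) -> list[WindowScore]:
    """Score sliding windows of ``cfg.window_n`` SNPs advanced by ``cfg.step``.

    Input must already be restricted to scoreable, pool-differentiated SNPs
    and be position-sorted within each chromosome.  With S surviving SNPs on
    a chromosome the window count is floor((S − n)/step) + 1 for S ≥ n, else
    0; trailing partial windows are dropped.  Windows never span chromosomes.
    """
    by_chrom: dict[str, list[BulkVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    windows: list[WindowScore] = []
    for chrom, group in by_chrom.items():
        pos = np.array([v.pos for v in group])
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"variants on {chrom} are not position-sorted")
        m = np.array([v.mutant.alt_frequency for v in group], dtype=float)
        w = np.array([v.wild.alt_frequency for v in group], dtype=float)
        if np.any(np.isnan(m)) or np.any(np.isnan(w)):
            raise ValueError(f"undefined allele frequency in scoring input on {chrom}")
        s = len(group)
        if s < cfg.window_n:
            continue
        for start in range(0, s - cfg.window_n + 1, cfg.step):
            end = start + cfg.window_n
            m_win, w_win = m[start:end], w[start:end]
            sd_m = sd_from_expectation(m_win, design.expected_af_mutant_bulk)
            sd_w = sd_from_expectation(w_win, design.expected_af_wild_bulk)
            score = varbscore_window(m_win, w_win, design, cfg.c, cfg.clamp_negative)
            windows.append(
                WindowScore(
                    chrom=chrom,
                    start_pos=int(pos[start]),
                    end_pos=int(pos[end - 1]),
                    n_snps=cfg.window_n,
                    sd_mutant=sd_m,
                    sd_wild=sd_w,
                    varbscore=score,
                    mean_delta_snp_index=snp_index_window(m_win, w_win),
                    rank_start=start,
                    rank_end=end - 1,
                )
            )
    return windows


def score_variants(
    variants: Sequence[BulkVariant],
    cfg: ScoreConfig | None = None,
    design: PopulationDesign | str = "f2_recessive",
    include_indels: bool = False,
) -> tuple[list[WindowScore], list[BulkVariant]]:
    """Full scoring pipeline: restrict to scoreable SNVs, apply the df filter,
    then score sliding windows.  Returns (windows, SNPs that entered windows).
    """
    from .variant_io import select_scoreable

    cfg = cfg or ScoreConfig()
    if isinstance(design, str):
        design = expected_frequencies(design)
    usable = select_scoreable(variants, include_indels=include_indels)
    kept = df_filter(usable, cfg.df_threshold)
    return sliding_windows(kept, cfg, design), kept


def windows_to_frame(windows: Iterable[WindowScore]) -> pd.DataFrame:
    rows = [
        {
            "chrom": wdw.chrom,
            "start": wdw.start_pos,
            "end": wdw.end_pos,
            "mid": wdw.mid_pos,
            "n_snps": wdw.n_snps,
            "sd_wild": wdw.sd_wild,
            "sd_mutant": wdw.sd_mutant,
            "varbscore": wdw.varbscore,
            "delta_snp_index": wdw.mean_delta_snp_index,
        }
        for wdw in windows
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "mid", "n_snps",
            "sd_wild", "sd_mutant", "varbscore", "delta_snp_index",
        ],
    )


def write_window_table(windows: Iterable[WindowScore], path: str | Path) -> Path:
    path = Path(path)
    windows_to_frame(windows).to_csv(path, sep="\t", index=False)
    return path


def plot_windows(windows: Sequence[WindowScore], path: str | Path, statistic: str = "varbscore") -> Path:
    """Manhattan-style plot of window scores at their genomic midpoints."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = windows_to_frame(windows)
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    for i, (chrom, grp) in enumerate(frame.groupby("chrom", sort=False)):
        ax.scatter(grp["mid"] + offset, grp[statistic], s=6,
                   color="C0" if i % 2 == 0 else "C1", label=chrom)
        offset += int(grp["end"].max()) if len(grp) else 0
    ax.set_xlabel("genomic position")
    ax.set_ylabel(statistic)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
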