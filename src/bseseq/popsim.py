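"""Synthetic bulked-segregant experiment generator.

Emulates the experiment the analysis assumes: an F2 (or backcross/RIL/DH)
population derived from crossing a recessive EMS mutant to a divergent
accession, segregating one causal mutation among many linked and unlinked
markers; phenotype-extreme bulks of ~30 individuals each; pooled short-read
sequencing at ~70× with binomial allele sampling and a small error rate; and
an EMS mutation spectrum that is >99% C→T / G→A.

Meiosis uses the Haldane map function r = (1 − e^(−2d))/2 (d in Morgans, no
crossover interference), applied between adjacent markers.  All mutant-line
alleles are simulated in coupling on one F1 haplotype, which matches a mutant
× wild cross where every marker's alternate allele originates from the
mutant parent.

Every random draw goes through a single :class:`numpy.random.Generator`
seeded from ``SimConfig.rng_seed``, so outputs are reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .variant_io import BulkObservation, BulkVariant, Genotype, write_bulk_vcf

__all__ = [
    "SimConfig",
    "SimTruth",
    "haldane",
    "simulate_f2_individual",
    "simulate_population",
    "select_bulks",
    "sample_reads",
    "generate_ems_sites",
    "draw_ems_alleles",
    "simulate_experiment",
    "write_simulation",
]

_EMS_ALT = {"C": "T", "G": "A"}
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic bulked-segregant experiment.

    Defaults mirror the study design the analysis targets: bulks of 30
    extreme-phenotype individuals from a 431-plant F2, ~70× pooled depth, an
    EMS spectrum ≥ 99.5% C→T/G→A, and one 500-Mb chromosome carrying 2,000
    segregating markers at 1 cM/Mb.
    """

    n_chromosomes: int = 1
    chrom_length_bp: int = 500_000_000
    genetic_map_cM_per_Mb: float = 1.0
    n_markers: int = 2000  # per chromosome
    causal_chrom: str | None = None  # default: first chromosome
    causal_pos: int | None = None  # default: chromosome midpoint
    design_name: str = "f2_recessive"
    population_size: int = 431
    bulk_size: int = 30
    mean_depth: float = 70.0
    sequencing_error_rate: float = 0.005
    ems_spectrum: float = 0.995
    wild_bulk_selection: str = "phenotype"  # or "homozygous" (F3-selected AA-only bulk)
    annotate: bool = True
    protein_altering_fraction: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.sequencing_error_rate < 0.5:
            raise ValueError("sequencing_error_rate must be in [0, 0.5)")
        if not 0.0 <= self.ems_spectrum <= 1.0:
            raise ValueError("ems_spectrum must be in [0, 1]")
        if self.n_markers < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one marker and one chromosome")
        if self.wild_bulk_selection not in ("phenotype", "homozygous"):
            raise ValueError("wild_bulk_selection must be 'phenotype' or 'homozygous'")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment, for parameter-recovery tests."""

    chroms: np.ndarray  # marker chromosome names
    positions: np.ndarray  # marker positions, 1-based
    genotypes: np.ndarray  # (population_size, n_markers) alt-allele dosage 0/1/2
    causal_key: tuple[str, int, str, str]
    wild_members: np.ndarray  # individual indices in the wild bulk
    mutant_members: np.ndarray
    true_wild_af: np.ndarray  # exact bulk alt-allele frequencies per marker
    true_mutant_af: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "pos": self.positions,
                "true_wild_af": self.true_wild_af,
                "true_mutant_af": self.true_mutant_af,
                "is_causal": [
                    (c, int(p)) == self.causal_key[:2]
                    for c, p in zip(self.chroms, self.positions)
                ],
            }
        )


def haldane(d_morgans: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction from genetic distance: r = (1 − e^(−2d)) / 2."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float))) / 2.0


def _recombination_fractions(positions: np.ndarray, cm_per_mb: float) -> np.ndarray:
    d_morgans = np.diff(positions) / 1e6 * cm_per_mb / 100.0
    return np.asarray(haldane(d_morgans))


def _draw_gametes(
    positions: np.ndarray, cm_per_mb: float, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Recombinant gametes from an F1 heterozygote with all alt alleles in
    coupling.  Returns an (n_gametes, n_markers) 0/1 array of alt alleles."""
    m = positions.size
    start = rng.random(n_gametes) < 0.5
    if m == 1:
        return start[:, None].astype(np.int8)
    r = _recombination_fractions(positions, cm_per_mb)
    crossovers = rng.random((n_gametes, m - 1)) < r
    parity = np.cumsum(crossovers, axis=1) % 2
    hap = np.concatenate([np.zeros((n_gametes, 1), dtype=np.int64), parity], axis=1)
    return (hap ^ start[:, None]).astype(np.int8)


def simulate_f2_individual(
    positions: Sequence[int], cm_per_mb: float, rng: np.random.Generator
) -> np.ndarray:
    """Alt-allele dosage vector (0/1/2) of one F2 individual.

    The individual is the union of two independent recombinant gametes from
    the F1 heterozygote; at any single marker the dosage is therefore
    distributed 0:1:2 = 1:2:1.
    """
    pos = np.asarray(positions, dtype=np.int64)
    gametes = _draw_gametes(pos, cm_per_mb, 2, rng)
    return gametes.sum(axis=0)


def simulate_population(
    positions: Sequence[int],
    cm_per_mb: float,
    n_individuals: int,
    rng: np.random.Generator,
    inbred: bool = False,
) -> np.ndarray:
    """Dosage matrix (n_individuals × n_markers) for one chromosome.

    ``inbred`` doubles a single gamete per individual (DH lines; RILs are
    approximated the same way, ignoring residual heterozygosity).
    """
    pos = np.asarray(positions, dtype=np.int64)
    if inbred:
        return 2 * _draw_gametes(pos, cm_per_mb, n_individuals, rng).astype(np.int16)
    gametes = _draw_gametes(pos, cm_per_mb, 2 * n_individuals, rng).astype(np.int16)
    return gametes[:n_individuals] + gametes[n_individuals:]


def select_bulks(
    genotypes: np.ndarray,
    causal_index: int,
    design_name: str,
    bulk_size: int,
    rng: np.random.Generator,
    wild_bulk_selection: str = "phenotype",
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the two phenotype-extreme bulks from the population.

    For a recessive design the mutant bulk is ``bulk_size`` individuals
    homozygous alt at the causal locus; the wild bulk is drawn from
    {hom_ref, het} ("phenotype" selection, the F2 case) or from hom_ref only
    ("homozygous", the F3 homozygous-selection variant).  For ``f2_dominant``
    the mutant-phenotype bulk is the alt-carrier class.  Raises when too few
    individuals qualify.
    """
    causal = genotypes[:, causal_index]
    if design_name == "f2_dominant":
        mutant_pool = np.flatnonzero(causal >= 1)
        wild_pool = np.flatnonzero(causal == 0)
    else:
        mutant_pool = np.flatnonzero(causal == 2)
        if wild_bulk_selection == "homozygous" or design_name in ("ril", "dh"):
            wild_pool = np.flatnonzero(causal == 0)
        else:
            wild_pool = np.flatnonzero(causal <= 1)
    for name, pool in (("mutant", mutant_pool), ("wild", wild_pool)):
        if pool.size < bulk_size:
            raise ValueError(
                f"only {pool.size} individuals qualify for the {name} bulk "
                f"(need {bulk_size}); simulate a larger population"
            )
    wild = rng.choice(wild_pool, size=bulk_size, replace=False)
    mutant = rng.choice(mutant_pool, size=bulk_size, replace=False)
    return np.sort(wild), np.sort(mutant)


def sample_reads(
    true_bulk_af: float | np.ndarray,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled read counts at one or more sites: total depth is
    Poisson(mean_depth) and the alt count Binomial(depth, af·(1−e)+(1−af)·e).

    Returns (ref_depth, alt_depth) arrays (or scalars for scalar input).
    """
    af = np.asarray(true_bulk_af, dtype=float)
    if np.any((af < 0) | (af > 1)):
        raise ValueError("true_bulk_af must be in [0, 1]")
    depth = rng.poisson(mean_depth, size=af.shape)
    p = af * (1.0 - error_rate) + (1.0 - af) * error_rate
    alt = rng.binomial(depth, p)
    return depth - alt, alt


def draw_ems_alleles(
    n: int, ems_spectrum: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(ref, alt) base pairs for n mutation sites under the EMS spectrum.

    With probability ``ems_spectrum`` a site is a C→T or G→A transition;
    otherwise the ref is uniform over ACGT and the alt uniform over the
    substitutions that are NOT the EMS change for that ref.
    """
    is_ems = rng.random(n) < ems_spectrum
    ref = _BASES[rng.integers(0, 4, size=n)]
    # EMS sites must sit on a C or G
    ref[is_ems] = np.where(rng.random(is_ems.sum()) < 0.5, "C", "G")
    alt = np.empty(n, dtype=ref.dtype)
    alt[is_ems] = np.array([_EMS_ALT[b] for b in ref[is_ems]])
    non = np.flatnonzero(~is_ems)
    for i in non:
        choices = [b for b in "ACGT" if b != ref[i] and _EMS_ALT.get(ref[i]) != b]
        alt[i] = choices[rng.integers(0, len(choices))]
    return ref, alt


def generate_ems_sites(
    reference: str,
    n_sites: int,
    ems_spectrum: float = 0.995,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, str, str]]:
    """Place n unique mutation sites on an explicit reference sequence.

    EMS draws (probability ``ems_spectrum``) pick a C/G position and apply the
    C→T / G→A change; other draws pick any remaining position and a uniform
    non-EMS substitution.  Positions are 1-based and unique.  Raises when the
    sequence cannot host the requested sites (too short, or no C/G available
    for the EMS draws).
    """
    rng = rng if rng is not None else np.random.default_rng()
    seq = np.array(list(reference.upper()))
    if n_sites > seq.size:
        raise ValueError(f"n_sites={n_sites} exceeds sequence length {seq.size}")
    n_ems = int(rng.binomial(n_sites, ems_spectrum))
    cg = np.flatnonzero((seq == "C") | (seq == "G"))
    if n_ems > cg.size:
        raise ValueError(
            f"need {n_ems} C/G positions for EMS-type sites but the sequence has {cg.size}"
        )
    ems_pos = rng.choice(cg, size=n_ems, replace=False)
    remaining = np.setdiff1d(np.arange(seq.size), ems_pos, assume_unique=False)
    n_other = n_sites - n_ems
    if n_other > remaining.size:
        raise ValueError("not enough positions left for non-EMS sites")
    other_pos = rng.choice(remaining, size=n_other, replace=False)

    sites: list[tuple[int, str, str]] = []
    for p in ems_pos:
        ref = seq[p]
        sites.append((int(p) + 1, str(ref), _EMS_ALT[str(ref)]))
    for p in other_pos:
        ref = str(seq[p])
        choices = [b for b in "ACGT" if b != ref and _EMS_ALT.get(ref) != b]
        sites.append((int(p) + 1, ref, choices[rng.integers(0, len(choices))]))
    sites.sort()
    return sites


def _unique_positions(length_bp: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n sorted unique 1-based positions on [1, length_bp], drawn without
    materialising the whole position range."""
    if n > length_bp:
        raise ValueError(f"cannot place {n} unique markers on {length_bp} bp")
    got: np.ndarray = np.empty(0, dtype=np.int64)
    while got.size < n:
        draw = rng.integers(1, length_bp + 1, size=2 * (n - got.size), dtype=np.int64)
        got = np.unique(np.concatenate([got, draw]))
    # thin deterministically to exactly n while keeping order random-free (sorted)
    if got.size > n:
        keep = rng.choice(got.size, size=n, replace=False)
        got = np.sort(got[keep])
    return got


def _bulk_genotype(af: float) -> Genotype:
    """Pooled pseudo-genotype from the TRUE bulk allele frequency, thresholded
    at 0.15 / 0.85 (an explicit convention; real pooled callers differ)."""
    if af < 0.15:
        return Genotype.HOM_REF
    if af > 0.85:
        return Genotype.HOM_ALT
    return Genotype.HET


def simulate_experiment(cfg: SimConfig) -> tuple[list[BulkVariant], SimTruth]:
    """Run one full in-silico bulked-segregant experiment.

    Returns the observed two-bulk variant list (the shape a VCF parse would
    produce) and the ground truth.  The causal marker is always an EMS-type
    transition annotated as a missense variant.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    chrom_names = cfg.chrom_names()
    causal_chrom = cfg.causal_chrom or chrom_names[0]
    if causal_chrom not in chrom_names:
        raise ValueError(f"causal_chrom {causal_chrom!r} not among {chrom_names}")
    causal_pos = cfg.causal_pos if cfg.causal_pos is not None else cfg.chrom_length_bp // 2

    inbred = cfg.design_name in ("ril", "dh")
    all_chroms: list[np.ndarray] = []
    all_pos: list[np.ndarray] = []
    geno_blocks: list[np.ndarray] = []
    causal_index = -1
    for chrom in chrom_names:
        pos = _unique_positions(cfg.chrom_length_bp, cfg.n_markers, rng)
        if chrom == causal_chrom:
            pos = np.unique(np.append(pos, np.int64(causal_pos)))
            causal_index = sum(p.size for p in all_pos) + int(
                np.searchsorted(pos, causal_pos)
            )
        # chromosomes are unlinked: independent meioses per chromosome
        geno_blocks.append(
            simulate_population(pos, cfg.genetic_map_cM_per_Mb, cfg.population_size, rng, inbred)
        )
        all_pos.append(pos)
        all_chroms.append(np.full(pos.size, chrom, dtype=object))

    genotypes = np.concatenate(geno_blocks, axis=1)
    positions = np.concatenate(all_pos)
    chroms = np.concatenate(all_chroms)
    n_markers = positions.size

    wild_idx, mutant_idx = select_bulks(
        genotypes, causal_index, cfg.design_name, cfg.bulk_size, rng, cfg.wild_bulk_selection
    )
    true_wild = genotypes[wild_idx].mean(axis=0) / 2.0
    true_mut = genotypes[mutant_idx].mean(axis=0) / 2.0

    ref, alt = draw_ems_alleles(n_markers, cfg.ems_spectrum, rng)
    ref[causal_index] = "C" if rng.random() < 0.5 else "G"
    alt[causal_index] = _EMS_ALT[str(ref[causal_index])]

    wild_ref, wild_alt = sample_reads(true_wild, cfg.mean_depth, cfg.sequencing_error_rate, rng)
    mut_ref, mut_alt = sample_reads(true_mut, cfg.mean_depth, cfg.sequencing_error_rate, rng)

    effects: list[list[tuple[str, str]]] = [[] for _ in range(n_markers)]
    if cfg.annotate:
        altering = rng.random(n_markers) < cfg.protein_altering_fraction
        for i in range(n_markers):
            gene = f"GENE{i:06d}"
            term = "missense_variant" if altering[i] else "synonymous_variant"
            effects[i] = [(term, gene)]
        effects[causal_index] = [("missense_variant", "GENE_CAUSAL")]

    variants = [
        BulkVariant(
            chrom=str(chroms[i]),
            pos=int(positions[i]),
            ref_allele=str(ref[i]),
            alt_allele=str(alt[i]),
            qual=100.0,
            wild=BulkObservation(int(wild_ref[i]), int(wild_alt[i]), _bulk_genotype(true_wild[i])),
            mutant=BulkObservation(int(mut_ref[i]), int(mut_alt[i]), _bulk_genotype(true_mut[i])),
            effects=effects[i],
        )
        for i in range(n_markers)
    ]
    truth = SimTruth(
        chroms=chroms,
        positions=positions,
        genotypes=genotypes,
        causal_key=(causal_chrom, int(causal_pos), str(ref[causal_index]), str(alt[causal_index])),
        wild_members=wild_idx,
        mutant_members=mutant_idx,
        true_wild_af=true_wild,
        true_mutant_af=true_mut,
    )
    return variants, truth


def write_simulation(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate one experiment and write VCF + truth TSV + config echo.

    The VCF carries samples ``wild_bulk`` and ``mutant_bulk`` with GT/AD/DP
    and (if configured) ANN annotations.  Outputs are bit-reproducible from
    ``cfg.rng_seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    variants, truth = simulate_experiment(cfg)

    vcf_path = out_dir / "simulated.vcf"
    write_bulk_vcf(
        variants,
        vcf_path,
        contig_lengths={c: cfg.chrom_length_bp for c in cfg.chrom_names()},
    )
    truth_path = out_dir / "truth.tsv"
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    config_path = out_dir / "sim_config.yaml"
    config_path.write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))
    return {"vcf": vcf_path, "truth": truth_path, "config": config_path}
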