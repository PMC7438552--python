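"""Reading, writing and filtering of two-bulk variant data.

A bulked-segregant experiment sequences two pooled DNA samples (a wild-type
bulk and a mutant bulk) as if each were a single individual.  The unit of
analysis is therefore a biallelic site together with the per-bulk allele
depths: how many reads in each pool support the reference allele and how many
support the alternate.  This module parses a standard multi-sample VCF into
that shape (:class:`BulkVariant`), applies the site-level quality filter used
upstream of the mapping statistic, and parses snpEff-style ``ANN`` annotation
strings into (effect, gene) pairs.

Coordinates are 1-based inclusive internally (VCF convention); BED output
elsewhere in the package is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

__all__ = [
    "Genotype",
    "BulkObservation",
    "BulkVariant",
    "QualityFilterConfig",
    "allele_frequency",
    "read_bulk_vcf",
    "write_bulk_vcf",
    "apply_quality_filter",
    "parse_effects",
    "select_scoreable",
    "variants_to_frame",
    "write_variant_table",
]

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


class Genotype(str, Enum):
    """Diploid (or pooled pseudo-diploid) genotype call relative to one alt allele."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class BulkObservation:
    """Read support for one allele pair in one bulk."""

    ref_depth: int
    alt_depth: int
    genotype: Genotype = Genotype.MISSING

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError(
                f"depths must be non-negative, got ({self.ref_depth}, {self.alt_depth})"
            )

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def alt_frequency(self) -> float | None:
        return allele_frequency(self.ref_depth, self.alt_depth)


@dataclass
class BulkVariant:
    """One biallelic site observed in the two bulks.

    ``effects`` holds (effect_term, gene_id) pairs from functional annotation,
    e.g. ``("missense_variant", "TraesCS7A02G480700")``.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    qual: float
    wild: BulkObservation
    mutant: BulkObservation
    effects: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in _VALID_BASES
            and self.alt_allele in _VALID_BASES
        )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class QualityFilterConfig:
    """Site-level quality filter: QUAL strictly above ``min_qual`` and at least
    ``min_depth`` reads in EACH bulk."""

    min_qual: float = 30.0
    min_depth: int = 5

    def __post_init__(self) -> None:
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


def allele_frequency(ref_depth: int, alt_depth: int) -> float | None:
    """Alternate-allele frequency ``alt / (ref + alt)``, the per-pool SNP-index.

    Returns ``None`` (undefined, not 0) when the site has no coverage.
    """
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError(f"depths must be non-negative, got ({ref_depth}, {alt_depth})")
    total = ref_depth + alt_depth
    if total == 0:
        return None
    return alt_depth / total


def _genotype_for_alt(alleles: tuple[int | None, ...] | None, alt_index: int) -> Genotype:
    """Genotype of one sample relative to alt number ``alt_index`` (1-based in GT).

    The per-alt call counts copies of that alt among the called alleles; an
    uncalled allele makes the genotype missing.
    """
    if alleles is None or len(alleles) == 0 or any(a is None for a in alleles):
        return Genotype.MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == len(alleles):
        return Genotype.HOM_ALT
    return Genotype.HET


def _observation(sample, alt_index: int) -> BulkObservation:
    """Extract one bulk's observation for one alt from a pysam sample record."""
    ad = sample.get("AD")
    if ad is None or len(ad) <= alt_index or ad[0] is None or ad[alt_index] is None:
        return BulkObservation(0, 0, Genotype.MISSING)
    gt = _genotype_for_alt(sample.get("GT"), alt_index)
    return BulkObservation(int(ad[0]), int(ad[alt_index]), gt)


def read_bulk_vcf(
    path: str | Path, wild_sample: str, mutant_sample: str
) -> list[BulkVariant]:
    """Read a two-bulk VCF into an ordered list of :class:`BulkVariant`.

    Multiallelic records are decomposed into one record per alt allele, each
    carrying that alt's depth from the per-sample ``AD`` field.  Records with
    no usable depth in a bulk get depths 0/0 and a missing genotype there.
    Output is sorted by (chromosome in order of first appearance, position).
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for name in (wild_sample, mutant_sample):
            if name not in samples:
                raise KeyError(
                    f"sample {name!r} not found in {path}; available samples: {samples}"
                )
        out: list[BulkVariant] = []
        chrom_order: dict[str, int] = {}
        for i, rec in enumerate(vcf, start=1):
            try:
                if rec.alts is None:
                    continue
                chrom_order.setdefault(rec.chrom, len(chrom_order))
                ann = rec.info.get("ANN") if "ANN" in rec.info else None
                if isinstance(ann, tuple):
                    ann = ",".join(ann)
                effects = parse_effects(ann) if ann else []
                for alt_index, alt in enumerate(rec.alts, start=1):
                    if alt is None or alt == rec.ref:
                        continue
                    out.append(
                        BulkVariant(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref_allele=rec.ref,
                            alt_allele=alt,
                            qual=float(rec.qual) if rec.qual is not None else 0.0,
                            wild=_observation(rec.samples[wild_sample], alt_index),
                            mutant=_observation(rec.samples[mutant_sample], alt_index),
                            effects=[e for e in effects if e[0]],
                        )
                    )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"unparseable VCF record #{i} in {path}: {exc}") from exc
    out.sort(key=lambda v: (chrom_order[v.chrom], v.pos))
    return out


_GT_CODES = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.MISSING: (None, None),
}


def write_bulk_vcf(
    variants: Sequence[BulkVariant],
    path: str | Path,
    wild_sample: str = "wild_bulk",
    mutant_sample: str = "mutant_bulk",
    contig_lengths: dict[str, int] | None = None,
) -> Path:
    """Write BulkVariants back out as an uncompressed two-sample VCF v4.2.

    Effects, if present, are serialised into a minimal snpEff-style ``ANN``
    INFO field so that a round trip through :func:`read_bulk_vcf` preserves
    depths, genotypes and (effect, gene) pairs.
    """
    path = Path(path)
    header = pysam.VariantHeader()
    seen: dict[str, int] = {}
    for v in variants:
        end = v.pos + max(len(v.ref_allele), 1)
        seen[v.chrom] = max(seen.get(v.chrom, 0), end)
    if contig_lengths:
        for c, length in contig_lengths.items():
            seen[c] = max(seen.get(c, 0), length)
    for c, length in seen.items():
        header.contigs.add(c, length=length)
    header.info.add("ANN", ".", "String", "Functional annotations: 'Allele|Annotation|Impact|Gene'")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.add_sample(wild_sample)
    header.add_sample(mutant_sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref_allele, v.alt_allele),
                qual=v.qual,
            )
            if v.effects:
                rec.info["ANN"] = ",".join(
                    f"{v.alt_allele}|{eff}|MODERATE|{gene}" for eff, gene in v.effects
                )
            for name, obs in ((wild_sample, v.wild), (mutant_sample, v.mutant)):
                rec.samples[name]["GT"] = _GT_CODES[obs.genotype]
                rec.samples[name]["AD"] = (obs.ref_depth, obs.alt_depth)
                rec.samples[name]["DP"] = obs.total_depth
            out.write(rec)
    return path


def apply_quality_filter(
    variants: Iterable[BulkVariant], cfg: QualityFilterConfig | None = None
) -> list[BulkVariant]:
    """Keep sites with QUAL strictly above the threshold and adequate depth in
    both bulks; input order is preserved."""
    cfg = cfg or QualityFilterConfig()
    return [
        v
        for v in variants
        if v.qual > cfg.min_qual
        and v.wild.total_depth >= cfg.min_depth
        and v.mutant.total_depth >= cfg.min_depth
    ]


def parse_effects(annotation: str | None) -> list[tuple[str, str]]:
    """Parse a snpEff-style ``ANN`` string into (effect_term, gene_id) pairs.

    The field is comma-separated over annotation alternatives; each alternative
    is pipe-delimited with the effect in sub-field 2 and the gene in sub-field
    4.  Effects joined with ``&`` are split into separate pairs.  Anything that
    does not fit that layout is skipped with a logged warning — the parser is
    deliberately lenient.
    """
    if not annotation:
        return []
    pairs: list[tuple[str, str]] = []
    for entry in annotation.split(","):
        fields = entry.split("|")
        if len(fields) < 4:
            log.warning("unrecognised ANN entry layout, skipping: %r", entry)
            continue
        gene = fields[3]
        for term in fields[1].split("&"):
            term = term.strip()
            if term:
                pairs.append((term, gene))
    return pairs


def select_scoreable(
    variants: Iterable[BulkVariant], include_indels: bool = False
) -> list[BulkVariant]:
    """Subset of variants eligible for window scoring: allele frequency defined
    in both bulks, genotype called in both bulks, and (by default) SNVs only."""
    out = []
    for v in variants:
        if v.wild.total_depth == 0 or v.mutant.total_depth == 0:
            continue
        if v.wild.genotype is Genotype.MISSING or v.mutant.genotype is Genotype.MISSING:
            continue
        if not include_indels and not v.is_snv:
            continue
        out.append(v)
    return out


def variants_to_frame(variants: Sequence[BulkVariant]) -> pd.DataFrame:
    """Flatten variants into the per-site TSV layout."""
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "qual": v.qual,
                "wild_ref": v.wild.ref_depth,
                "wild_alt": v.wild.alt_depth,
                "mut_ref": v.mutant.ref_depth,
                "mut_alt": v.mutant.alt_depth,
                "wild_af": v.wild.alt_frequency,
                "mut_af": v.mutant.alt_frequency,
                "wild_gt": v.wild.genotype.value,
                "mut_gt": v.mutant.genotype.value,
                "effects": ";".join(f"{e}:{g}" for e, g in v.effects),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "qual",
            "wild_ref", "wild_alt", "mut_ref", "mut_alt",
            "wild_af", "mut_af", "wild_gt", "mut_gt", "effects",
        ],
    )


def write_variant_table(variants: Sequence[BulkVariant], path: str | Path) -> Path:
    path = Path(path)
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)
    return path
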