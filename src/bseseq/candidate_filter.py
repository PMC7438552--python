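"""EMS-oriented candidate filter cascade.

After window scoring localises the signal, the list of differentiated SNPs is
reduced to a handful of candidate causal mutations by four successive
predicates reflecting how an EMS mutant is built and expressed:

1. allelic difference — the two bulks are opposite homozygotes (one matches
   the reference, the other is fixed for the alternate, in either
   orientation);
2. EMS type — EMS almost exclusively induces C:G→T:A transitions, so the
   ref→alt pair must be C→T or G→A (read literally on the VCF forward
   strand, which already covers both strands of the transition);
3. effect — the causal lesion must alter the protein, so only
   protein-altering annotation terms are retained;
4. background — any variant also present in unrelated materials sharing the
   wild phenotype cannot be causal and is removed.

Each filter is a pure predicate, so the final set is order-independent; the
per-stage counts in the report follow the fixed order above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .variant_io import BulkVariant, Genotype

__all__ = [
    "PROTEIN_ALTERING_EFFECTS",
    "BackgroundPanel",
    "FilterCascadeReport",
    "is_ems_transition",
    "allelic_difference_filter",
    "ems_type_filter",
    "effect_filter",
    "background_filter",
    "run_cascade",
    "candidate_table",
]

log = logging.getLogger(__name__)

#: Annotation terms counted as protein-altering: missense, loss of start/stop,
#: gain of a stop, and coding-sequence insertions/deletions.
PROTEIN_ALTERING_EFFECTS: frozenset[str] = frozenset(
    {
        "missense_variant",
        "start_lost",
        "stop_lost",
        "stop_gained",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "conservative_inframe_insertion",
        "conservative_inframe_deletion",
        "disruptive_inframe_insertion",
        "disruptive_inframe_deletion",
    }
)

_EMS_PAIRS = frozenset({("C", "T"), ("G", "A")})


def is_ems_transition(ref: str, alt: str) -> bool:
    """True for the canonical EMS-induced changes C→T and G→A (forward strand)."""
    return (ref, alt) in _EMS_PAIRS


@dataclass
class BackgroundPanel:
    """Set of (chrom, pos, ref, alt) keys seen in background materials."""

    keys: set[tuple[str, int, str, str]] = field(default_factory=set)

    @classmethod
    def from_variants(cls, variants: Iterable[BulkVariant]) -> "BackgroundPanel":
        return cls({v.key for v in variants})

    @classmethod
    def from_vcf(cls, path: str | Path) -> "BackgroundPanel":
        import pysam

        keys: set[tuple[str, int, str, str]] = set()
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if rec.alts is None:
                    continue
                for alt in rec.alts:
                    if alt is not None:
                        keys.add((rec.chrom, rec.pos, rec.ref, alt))
        return cls(keys)

    @classmethod
    def from_table(cls, path: str | Path) -> "BackgroundPanel":
        """Load a 4-column (chrom, pos, ref, alt) TSV, with or without header."""
        frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if frame.shape[1] < 4:
            raise ValueError(f"background table {path} needs 4 columns, has {frame.shape[1]}")
        first = frame.iloc[0]
        if not str(first[1]).isdigit():  # header row
            frame = frame.iloc[1:]
        return cls(
            {
                (str(r[0]), int(r[1]), str(r[2]), str(r[3]))
                for r in frame.itertuples(index=False)
            }
        )

    @classmethod
    def load(cls, path: str | Path) -> "BackgroundPanel":
        p = str(path)
        if p.endswith((".vcf", ".vcf.gz", ".bcf")):
            return cls.from_vcf(p)
        return cls.from_table(p)

    def __contains__(self, variant: BulkVariant) -> bool:
        return variant.key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


def allelic_difference_filter(
    variants: Iterable[BulkVariant], af_fallback: bool = False
) -> list[BulkVariant]:
    """Keep variants where one bulk is homozygous reference and the other
    homozygous alternate, in either orientation.

    Heterozygous or missing genotypes fail the filter; with ``af_fallback``,
    a missing genotype call is substituted by thresholding the bulk's allele
    frequency (≤ 0.1 → hom_ref, ≥ 0.9 → hom_alt).
    """

    def effective_gt(obs) -> Genotype:
        if obs.genotype is not Genotype.MISSING or not af_fallback:
            return obs.genotype
        af = obs.alt_frequency
        if af is None:
            return Genotype.MISSING
        if af <= 0.1:
            return Genotype.HOM_REF
        if af >= 0.9:
            return Genotype.HOM_ALT
        return Genotype.MISSING

    passing = {
        (Genotype.HOM_REF, Genotype.HOM_ALT),
        (Genotype.HOM_ALT, Genotype.HOM_REF),
    }
    return [
        v for v in variants if (effective_gt(v.wild), effective_gt(v.mutant)) in passing
    ]


def ems_type_filter(variants: Iterable[BulkVariant]) -> list[BulkVariant]:
    """Keep only C→T and G→A single-nucleotide changes."""
    return [v for v in variants if is_ems_transition(v.ref_allele, v.alt_allele)]


def effect_filter(
    variants: Iterable[BulkVariant],
    retained_effects: frozenset[str] | set[str] | None = None,
) -> list[BulkVariant]:
    """Keep variants annotated with at least one protein-altering effect term
    (set-intersection semantics over the variant's effect list)."""
    retained = frozenset(retained_effects) if retained_effects is not None else PROTEIN_ALTERING_EFFECTS
    return [v for v in variants if retained.intersection(e for e, _ in v.effects)]


def background_filter(
    variants: Iterable[BulkVariant], panel: BackgroundPanel | None
) -> list[BulkVariant]:
    """Remove variants whose (chrom, pos, ref, alt) key appears in the panel."""
    if panel is None or len(panel) == 0:
        return list(variants)
    return [v for v in variants if v not in panel]


@dataclass
class FilterCascadeReport:
    """Per-stage survivor counts plus the final candidate list."""

    total_diff_snps: int
    after_allelic_difference: int
    after_ems_type: int
    after_effect: int
    after_background: int
    survivors: list[BulkVariant] = field(default_factory=list)

    def counts(self) -> list[tuple[str, int]]:
        return [
            ("input", self.total_diff_snps),
            ("allelic_difference", self.after_allelic_difference),
            ("ems_type", self.after_ems_type),
            ("effect", self.after_effect),
            ("background", self.after_background),
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts(), columns=["stage", "count"])


def run_cascade(
    variants: Sequence[BulkVariant],
    panel: BackgroundPanel | None = None,
    retained_effects: frozenset[str] | set[str] | None = None,
    af_fallback: bool = False,
) -> FilterCascadeReport:
    """Apply allelic-difference → EMS-type → effect → background in order,
    recording the survivor count after each stage.

    Expects site-quality filtering to have been applied already.
    """
    variants = list(variants)
    s1 = allelic_difference_filter(variants, af_fallback=af_fallback)
    s2 = ems_type_filter(s1)
    s3 = effect_filter(s2, retained_effects)
    s4 = background_filter(s3, panel)
    return FilterCascadeReport(
        total_diff_snps=len(variants),
        after_allelic_difference=len(s1),
        after_ems_type=len(s2),
        after_effect=len(s3),
        after_background=len(s4),
        survivors=s4,
    )


def candidate_table(variants: Sequence[BulkVariant]) -> pd.DataFrame:
    """Candidate table with per-pool depths and gene annotations, one row per
    surviving variant: Chr, Pos, Reference, MutantBase, Feature, Gene,
    WildtypePool (ref|alt), MutantPool (ref|alt)."""
    rows = []
    for v in variants:
        feature, gene = (v.effects[0] if v.effects else ("", ""))
        rows.append(
            {
                "Chr": v.chrom,
                "Pos": v.pos,
                "Reference": v.ref_allele,
                "MutantBase": v.alt_allele,
                "Feature": feature,
                "Gene": gene,
                "WildtypePool": f"{v.wild.ref_depth}|{v.wild.alt_depth}",
                "MutantPool": f"{v.mutant.ref_depth}|{v.mutant.alt_depth}",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Chr", "Pos", "Reference", "MutantBase",
            "Feature", "Gene", "WildtypePool", "MutantPool",
        ],
    )
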