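"""Shared fixtures: hand-built variants and a transcribed candidate-table VCF."""

from __future__ import annotations

from pathlib import Path

import pytest

from bseseq.variant_io import BulkObservation, BulkVariant, Genotype

# The seven published candidate SNPs on wheat chromosome 7A (~671 Mb region):
# (pos, ref, alt, gene, wild ref|alt depths, mutant ref|alt depths).  All are
# C→T / G→A missense changes with opposite homozygous genotypes in the pools;
# row 5 (TraesCS7A02G480700, Mg-chelatase subunit chlI) is the causal one.
TABLE2_ROWS = [
    (630_870_068, "G", "A", "TraesCS7A02G436400", (5, 0), (0, 5)),
    (655_451_742, "C", "T", "TraesCS7A02G460100", (31, 0), (2, 32)),
    (662_134_333, "C", "T", "TraesCS7A02G465600", (11, 0), (0, 6)),
    (662_143_366, "C", "T", "TraesCS7A02G465700", (38, 0), (1, 19)),
    (672_873_436, "C", "T", "TraesCS7A02G480700", (34, 0), (0, 53)),
    (680_628_523, "C", "T", "TraesCS7A02G492000", (18, 0), (1, 10)),
    (682_175_198, "C", "T", "TraesCS7A02G493600", (4, 0), (0, 4)),
]


def mk_variant(
    chrom="chr1",
    pos=100,
    ref="C",
    alt="T",
    qual=100.0,
    wild=(30, 0),
    mutant=(0, 30),
    wild_gt=Genotype.HOM_REF,
    mut_gt=Genotype.HOM_ALT,
    effects=None,
) -> BulkVariant:
    return BulkVariant(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        qual=qual,
        wild=BulkObservation(*wild, wild_gt),
        mutant=BulkObservation(*mutant, mut_gt),
        effects=effects if effects is not None else [("missense_variant", "GENE1")],
    )


@pytest.fixture
def table2_variants() -> list[BulkVariant]:
    return [
        mk_variant(
            chrom="chr7A",
            pos=pos,
            ref=ref,
            alt=alt,
            wild=wd,
            mutant=md,
            effects=[("missense_variant", gene)],
        )
        for pos, ref, alt, gene, wd, md in TABLE2_ROWS
    ]


@pytest.fixture
def table2_vcf(tmp_path: Path) -> Path:
    """The seven candidate SNPs written as a literal two-sample VCF."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr7A,length=736706236>",
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\twild_bulk\tmutant_bulk",
    ]
    for pos, ref, alt, gene, (wr, wa), (mr, ma) in TABLE2_ROWS:
        ann = f"ANN={alt}|missense_variant|MODERATE|{gene}"
        lines.append(
            f"chr7A\t{pos}\t.\t{ref}\t{alt}\t100\tPASS\t{ann}\tGT:AD:DP"
            f"\t0/0:{wr},{wa}:{wr + wa}\t1/1:{mr},{ma}:{mr + ma}"
        )
    path = tmp_path / "table2.vcf"
    path.write_text("\n".join(lines) + "\n")
    return path
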