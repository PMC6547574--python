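"""Pairwise sample comparison: comparable and differential SSR loci.

A locus is *comparable* between two samples when its call is valid in
both; it is *differential* when the two genotype strings differ.  String
equality is deliberate: sequencing distinguishes same-length alleles
with different base composition, which electrophoresis cannot.  Each
differential locus is binned by absolute amplicon-length difference into
0 bp (electrophoretically indistinguishable), 1-5 bp (hardly
distinguishable) and > 5 bp (distinguishable) classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .genotyping import GenotypeCall, genotype_length

__all__ = [
    "BIN_ZERO",
    "BIN_SMALL",
    "BIN_LARGE",
    "ComparisonRecord",
    "ComparisonSummary",
    "comparable_loci",
    "length_diff_bin",
    "compare_samples",
    "national_standard_subset",
    "round_percent",
]

BIN_ZERO = "0"
BIN_SMALL = "1–5"   # 1–5 bp
BIN_LARGE = ">5"


@dataclass
class ComparisonRecord:
    locus_id: str
    genotype_a: str
    genotype_b: str
    differential: bool
    length_diff_bp: int
    bin: Optional[str]          # set only for differential loci
    chromosome: Optional[str] = None


@dataclass
class ComparisonSummary:
    n_comparable: int
    n_differential: int
    pct_differential: float     # percent, rounded half-up to one decimal
    bins: Dict[str, int] = field(default_factory=dict)
    per_chromosome: Dict[str, int] = field(default_factory=dict)


def round_percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal place (0.0 for an empty
    denominator)."""
    if denominator == 0:
        return 0.0
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def length_diff_bin(length_diff_bp: int) -> str:
    if length_diff_bp < 0:
        raise ValueError("length difference must be non-negative")
    if length_diff_bp == 0:
        return BIN_ZERO
    if length_diff_bp <= 5:
        return BIN_SMALL
    return BIN_LARGE


def _locus_sort_key(panel_positions: Optional[Mapping[str, Tuple[str, int]]]):
    def key(locus_id: str):
        if panel_positions and locus_id in panel_positions:
            chrom, pos = panel_positions[locus_id]
            return (0, chrom, pos, locus_id)
        return (1, "", 0, locus_id)

    return key


def comparable_loci(
    sample_a: Mapping[str, GenotypeCall],
    sample_b: Mapping[str, GenotypeCall],
    panel_positions: Optional[Mapping[str, Tuple[str, int]]] = None,
) -> List[str]:
    """Loci valid in both samples, ordered by chromosome and position
    when the panel provides coordinates (locus id otherwise)."""
    shared = [
        locus_id
        for locus_id, call in sample_a.items()
        if call.valid and locus_id in sample_b and sample_b[locus_id].valid
    ]
    shared.sort(key=_locus_sort_key(panel_positions))
    return shared


def compare_samples(
    sample_a: Mapping[str, GenotypeCall],
    sample_b: Mapping[str, GenotypeCall],
    panel_positions: Optional[Mapping[str, Tuple[str, int]]] = None,
) -> Tuple[List[ComparisonRecord], ComparisonSummary]:
    """Compare two samples' genotype tables locus by locus.

    Returns one record per comparable locus plus a summary with the
    differential percentage, length-difference bins over the
    differential loci, and comparable counts per chromosome.
    """
    records: List[ComparisonRecord] = []
    for locus_id in comparable_loci(sample_a, sample_b, panel_positions):
        ga = sample_a[locus_id].genotype
        gb = sample_b[locus_id].genotype
        differential = ga != gb
        diff = abs(genotype_length(ga) - genotype_length(gb)) if differential else 0
        chrom = None
        if panel_positions and locus_id in panel_positions:
            chrom = panel_positions[locus_id][0]
        records.append(
            ComparisonRecord(
                locus_id=locus_id,
                genotype_a=ga,
                genotype_b=gb,
                differential=differential,
                length_diff_bp=diff,
                bin=length_diff_bin(diff) if differential else None,
                chromosome=chrom,
            )
        )
    return records, summarize(records)


def summarize(records: Sequence[ComparisonRecord]) -> ComparisonSummary:
    n_comparable = len(records)
    differential = [r for r in records if r.differential]
    bins = {BIN_ZERO: 0, BIN_SMALL: 0, BIN_LARGE: 0}
    for rec in differential:
        bins[rec.bin] += 1
    per_chrom: Dict[str, int] = {}
    for rec in records:
        if rec.chromosome is not None:
            per_chrom[rec.chromosome] = per_chrom.get(rec.chromosome, 0) + 1
    return ComparisonSummary(
        n_comparable=n_comparable,
        n_differential=len(differential),
        pct_differential=round_percent(len(differential), n_comparable),
        bins=bins,
        per_chromosome=per_chrom,
    )


def national_standard_subset(
    records: Sequence[ComparisonRecord],
    standard_loci: Mapping[str, str],
) -> ComparisonSummary:
    """Summary restricted to loci carrying a national-standard marker
    name (``standard_loci`` maps locus id to marker name)."""
    subset = [r for r in records if standard_loci.get(r.locus_id)]
    return summarize(subset)
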