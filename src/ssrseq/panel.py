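"""Diversity-index computation and target-panel selection.

A locus's diversity index is the fraction of variety pairs it can
distinguish: pairs where both varieties carry a valid call and the two
genotype strings differ, divided by the total number of pairs C(n, 2).
The denominator is fixed by the number of varieties regardless of
missing or invalid calls, so a poorly amplifying locus scores low.

Panel selection keeps loci whose diversity index exceeds a threshold
(strictly) and that sit within a maximum genomic distance of another
passing locus on the same chromosome, enforcing both polymorphism and
genome coverage density.  A chromosome's only passing locus is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, List, Mapping, Optional, Sequence

from .genotyping import GenotypeCall

__all__ = [
    "DiversityRecord",
    "DEFAULT_MIN_DIVERSITY",
    "DEFAULT_MAX_GAP_BP",
    "diversity_index",
    "select_target_loci",
]

DEFAULT_MIN_DIVERSITY = 0.3
DEFAULT_MAX_GAP_BP = 1_000_000


@dataclass
class DiversityRecord:
    locus_id: str
    distinguishable_pairs: int
    total_pairs: int
    diversity_index: float
    chromosome: Optional[str] = None
    position: Optional[int] = None  # tract start, 1-based
    selected: bool = False


def diversity_index(
    locus_id: str,
    calls: Mapping[str, Optional[GenotypeCall]],
    n_varieties: int,
    chromosome: Optional[str] = None,
    position: Optional[int] = None,
) -> DiversityRecord:
    """Diversity index of one locus across ``n_varieties`` varieties.

    ``calls`` maps variety name to the locus's call in that variety
    (``None`` or an absent key for undetected loci).  A pair counts as
    distinguishable only when both calls exist, both are valid, and the
    genotype strings differ.
    """
    if n_varieties < 2:
        raise ValueError("need at least two varieties")
    valid = {
        v: c.genotype
        for v, c in calls.items()
        if c is not None and c.valid
    }
    distinguishable = sum(
        1 for a, b in combinations(sorted(valid), 2) if valid[a] != valid[b]
    )
    total = comb(n_varieties, 2)
    return DiversityRecord(
        locus_id=locus_id,
        distinguishable_pairs=distinguishable,
        total_pairs=total,
        diversity_index=distinguishable / total,
        chromosome=chromosome,
        position=position,
    )


def select_target_loci(
    records: Sequence[DiversityRecord],
    min_diversity: float = DEFAULT_MIN_DIVERSITY,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> List[DiversityRecord]:
    """Select target loci by polymorphism and genomic spacing.

    A locus passes when its diversity index is strictly greater than
    ``min_diversity`` and the distance (between tract starts) to the
    nearest other diversity-passing locus on its chromosome is strictly
    below ``max_gap_bp``.  A chromosome carrying a single passing locus
    keeps it.  Sets ``selected`` on the input records and returns the
    selected subset sorted by chromosome then position.
    """
    if not 0 <= min_diversity <= 1:
        raise ValueError("min_diversity must be in [0, 1]")
    for rec in records:
        rec.selected = False
    candidates = [r for r in records if r.diversity_index > min_diversity]
    by_chrom: Dict[str, List[DiversityRecord]] = {}
    for rec in candidates:
        if rec.chromosome is None or rec.position is None:
            raise ValueError(f"locus {rec.locus_id} lacks a genomic position")
        by_chrom.setdefault(rec.chromosome, []).append(rec)

    selected: List[DiversityRecord] = []
    for chrom_records in by_chrom.values():
        chrom_records.sort(key=lambda r: r.position)
        if len(chrom_records) == 1:
            chrom_records[0].selected = True
            selected.append(chrom_records[0])
            continue
        positions = [r.position for r in chrom_records]
        for i, rec in enumerate(chrom_records):
            gaps = []
            if i > 0:
                gaps.append(positions[i] - positions[i - 1])
            if i < len(positions) - 1:
                gaps.append(positions[i + 1] - positions[i])
            if min(gaps) < max_gap_bp:
                rec.selected = True
                selected.append(rec)
    selected.sort(key=lambda r: (r.chromosome, r.position))
    return selected
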