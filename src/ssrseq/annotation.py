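"""Genomic-region classification of SSR loci and frameshift assessment.

Loci are placed into one of four region classes from gene models:
CDS, UTR, intron or intergenic, with precedence CDS > UTR > intron for
tracts straddling a boundary (one base of overlap suffices).  Repeat
type is the motif length class (mono- through hexanucleotide).  For a
differential locus inside a CDS, a repeat-length change whose base-pair
difference is a multiple of three preserves the reading frame
(frameshift-free); any other CDS change is a frameshift.  Outside the
CDS the notion does not apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import gffutils

from .comparison import ComparisonRecord
from .genotyping import Locus

__all__ = [
    "GeneModel",
    "REGION_CDS",
    "REGION_UTR",
    "REGION_INTRON",
    "REGION_INTERGENIC",
    "REPEAT_TYPES",
    "load_gene_models",
    "classify_region",
    "overlapping_gene",
    "repeat_type",
    "frameshift_status",
]

logger = logging.getLogger(__name__)

REGION_CDS = "CDS"
REGION_UTR = "UTR"
REGION_INTRON = "intron"
REGION_INTERGENIC = "intergenic"

REPEAT_TYPES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

FS_NOT_APPLICABLE = "not_applicable"
FS_FREE = "frameshift_free"
FS_SHIFT = "frameshift"

Interval = Tuple[int, int]  # 1-based inclusive


@dataclass
class GeneModel:
    """One gene's span and feature intervals (1-based inclusive)."""

    gene_id: str
    chromosome: str
    strand: str
    span: Interval
    cds: List[Interval] = field(default_factory=list)
    utr: List[Interval] = field(default_factory=list)
    exons: List[Interval] = field(default_factory=list)


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def load_gene_models(gff3_path: str) -> Dict[str, List[GeneModel]]:
    """Parse a GFF3 file into gene models indexed by chromosome.

    Consumes gene, CDS, five_prime_UTR/three_prime_UTR and exon features;
    sub-features are attributed to the enclosing gene via Parent links.
    """
    db = gffutils.create_db(
        gff3_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: Dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        models[gene.id] = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            span=(gene.start, gene.end),
        )
    feature_slots = {
        "CDS": "cds",
        "five_prime_UTR": "utr",
        "three_prime_UTR": "utr",
        "exon": "exons",
    }
    for ftype, slot in feature_slots.items():
        for feat in db.features_of_type(ftype):
            for gene_id in _ancestor_genes(db, feat):
                if gene_id in models:
                    getattr(models[gene_id], slot).append((feat.start, feat.end))
    by_chrom: Dict[str, List[GeneModel]] = {}
    for model in models.values():
        by_chrom.setdefault(model.chromosome, []).append(model)
    for chrom_models in by_chrom.values():
        chrom_models.sort(key=lambda m: m.span[0])
    return by_chrom


def _ancestor_genes(db, feat) -> List[str]:
    genes = set()
    stack = list(feat.attributes.get("Parent", []))
    seen = set()
    while stack:
        pid = stack.pop()
        if pid in seen:
            continue
        seen.add(pid)
        try:
            parent = db[pid]
        except gffutils.FeatureNotFoundError:
            continue
        if parent.featuretype == "gene":
            genes.add(parent.id)
        else:
            stack.extend(parent.attributes.get("Parent", []))
    return sorted(genes)


def classify_region(locus: Locus, models: Mapping[str, List[GeneModel]]) -> str:
    """Region class of a locus under precedence CDS > UTR > intron.

    A tract inside a gene span that overlaps no exon is intronic; a
    tract outside every gene span (or on a chromosome absent from the
    gene models) is intergenic.
    """
    tract = (locus.start, locus.end)
    chrom_models = models.get(locus.chromosome)
    if chrom_models is None:
        logger.warning(
            "chromosome %s absent from gene models; locus %s classified intergenic",
            locus.chromosome,
            locus.locus_id,
        )
        return REGION_INTERGENIC
    in_gene = False
    in_exon = False
    for model in chrom_models:
        if not _overlaps(tract, model.span):
            continue
        if any(_overlaps(tract, iv) for iv in model.cds):
            return REGION_CDS
        if any(_overlaps(tract, iv) for iv in model.utr):
            return REGION_UTR
        in_gene = True
        if any(_overlaps(tract, iv) for iv in model.exons):
            in_exon = True
    if in_gene and not in_exon:
        return REGION_INTRON
    return REGION_INTERGENIC


def overlapping_gene(locus: Locus, models: Mapping[str, List[GeneModel]]) -> Optional[str]:
    """Id of the first gene (by start) whose span overlaps the tract."""
    tract = (locus.start, locus.end)
    for model in models.get(locus.chromosome, []):
        if _overlaps(tract, model.span):
            return model.gene_id
    return None


def repeat_type(motif: str) -> str:
    """Repeat class by motif length: mono (1) through hexa (6)."""
    if len(motif) not in REPEAT_TYPES:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    return REPEAT_TYPES[len(motif)]


def frameshift_status(record: ComparisonRecord, region: str) -> str:
    """Frame effect of a differential repeat variant.

    Only CDS variants are assessed: frameshift-free when the length
    difference is a multiple of 3 (e.g. any trinucleotide repeat-count
    change), frameshift otherwise.
    """
    if not record.differential:
        raise ValueError("frameshift status is defined for differential loci only")
    if region != REGION_CDS:
        return FS_NOT_APPLICABLE
    return FS_FREE if record.length_diff_bp % 3 == 0 else FS_SHIFT
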