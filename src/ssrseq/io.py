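"""Readers and writers for the package's file formats.

Tabular formats are tab-separated text with a ``#``-prefixed header
line; coordinates are 1-based inclusive throughout.  FASTA/FASTQ go
through Biopython, SAM through pysam (only the read sequence and strand
bit are consulted), GFF3 through the annotation module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__ as _version
from .comparison import ComparisonRecord, ComparisonSummary
from .genotyping import (
    GenotypeCall,
    SSRLocus,
    apply_validity_filter,
    parse_genotype,
    reverse_complement,
)
from .panel import DiversityRecord
from .simulate import SimTruth

logger = logging.getLogger(__name__)

__all__ = [
    "TableFormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq_sequences",
    "write_fastq",
    "read_sam_sequences",
    "read_panel",
    "write_panel",
    "read_genotype_table",
    "write_genotype_table",
    "write_truth_table",
    "read_truth_table",
    "write_diversity_table",
    "write_comparison_table",
    "write_annotation_table",
    "write_summary_json",
    "panel_positions",
]

_MISSING = "."


class TableFormatError(ValueError):
    """Raised after collecting all row-level errors of a malformed table."""

    def __init__(self, path: str, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors)
        )


def _provenance_line(params: Optional[Mapping[str, object]] = None) -> str:
    blob = {"generator": f"ssrseq {_version}"}
    if params:
        blob.update(params)
    return "## " + json.dumps(blob, sort_keys=True)


# -- sequences --------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq_sequences(
    path: Union[str, Path],
    min_mean_quality: Optional[float] = None,
) -> List[str]:
    """Read sequences from FASTQ, optionally dropping reads whose mean
    Phred quality falls below ``min_mean_quality`` (off by default)."""
    sequences = []
    n_dropped = 0
    for rec in SeqIO.parse(str(path), "fastq"):
        if min_mean_quality is not None:
            quals = rec.letter_annotations["phred_quality"]
            if quals and sum(quals) / len(quals) < min_mean_quality:
                n_dropped += 1
                continue
        sequences.append(str(rec.seq).upper())
    if n_dropped:
        logger.info("%s: dropped %d reads below mean quality %.1f",
                    path, n_dropped, min_mean_quality)
    return sequences


def write_fastq(reads: Iterable[Tuple[str, str]], path: Union[str, Path]) -> None:
    """Write ``(read_id, sequence)`` pairs with a constant quality string."""
    with open(path, "w") as handle:
        for read_id, seq in reads:
            handle.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_sam_sequences(path: Union[str, Path]) -> List[str]:
    """Read sequences from a SAM file, restoring the sequencing strand.

    Only SEQ and the reverse-strand FLAG bit are consulted; typing
    itself re-anchors on the flanks, so mapped coordinates are ignored.
    """
    sequences = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            seq = aln.query_sequence
            if seq is None:
                continue
            if aln.is_reverse:
                seq = reverse_complement(seq)
            sequences.append(seq.upper())
    return sequences


# -- locus panel ------------------------------------------------------------

_PANEL_COLUMNS = [
    "locus_id",
    "amplicon_id",
    "chromosome",
    "start",
    "end",
    "motif",
    "ref_repeat_count",
    "left_flank",
    "right_flank",
    "national_standard_name",
]


def write_panel(loci: Sequence[SSRLocus], path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        handle.write(_provenance_line() + "\n")
        handle.write("#" + "\t".join(_PANEL_COLUMNS) + "\n")
        for locus in loci:
            handle.write(
                "\t".join(
                    [
                        locus.locus_id,
                        locus.amplicon_id,
                        locus.chromosome,
                        str(locus.start),
                        str(locus.end),
                        locus.motif,
                        str(locus.ref_repeat_count),
                        locus.left_flank,
                        locus.right_flank,
                        locus.national_standard_name or _MISSING,
                    ]
                )
                + "\n"
            )


def read_panel(path: Union[str, Path]) -> List[SSRLocus]:
    loci: List[SSRLocus] = []
    errors: List[str] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_PANEL_COLUMNS):
                errors.append(f"line {lineno}: expected {len(_PANEL_COLUMNS)} columns")
                continue
            try:
                name = fields[9] if fields[9] != _MISSING else None
                loci.append(
                    SSRLocus(
                        locus_id=fields[0],
                        amplicon_id=fields[1],
                        chromosome=fields[2],
                        start=int(fields[3]),
                        end=int(fields[4]),
                        motif=fields[5],
                        ref_repeat_count=int(fields[6]),
                        left_flank=fields[7],
                        right_flank=fields[8],
                        national_standard_name=name,
                    )
                )
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise TableFormatError(str(path), errors)
    return loci


def panel_positions(loci: Sequence[SSRLocus]) -> Dict[str, Tuple[str, int]]:
    """Map simple and merged locus ids to (chromosome, tract start)."""
    positions: Dict[str, Tuple[str, int]] = {}
    by_amplicon: Dict[str, List[SSRLocus]] = {}
    for locus in loci:
        positions[locus.locus_id] = (locus.chromosome, locus.start)
        by_amplicon.setdefault(locus.amplicon_id, []).append(locus)
    from .genotyping import merge_nearby_loci

    for amp_loci in by_amplicon.values():
        for merged in merge_nearby_loci(amp_loci):
            positions[merged.locus_id] = (merged.chromosome, merged.start)
    return positions


# -- genotype tables --------------------------------------------------------

_GENOTYPE_COLUMNS = [
    "sample",
    "amplicon_id",
    "locus_id",
    "genotype",
    "coverage",
    "stutter_ratio",
    "valid",
]


def write_genotype_table(
    calls: Mapping[str, GenotypeCall],
    sample: str,
    path: Union[str, Path],
    amplicon_ids: Optional[Mapping[str, str]] = None,
    params: Optional[Mapping[str, object]] = None,
) -> None:
    with open(path, "w") as handle:
        handle.write(_provenance_line(params) + "\n")
        handle.write("#" + "\t".join(_GENOTYPE_COLUMNS) + "\n")
        for locus_id in sorted(calls):
            call = calls[locus_id]
            amplicon = (amplicon_ids or {}).get(locus_id, _MISSING)
            handle.write(
                "\t".join(
                    [
                        sample,
                        amplicon,
                        locus_id,
                        call.genotype,
                        str(call.coverage),
                        f"{call.stutter_ratio:.4f}",
                        "1" if call.valid else "0",
                    ]
                )
                + "\n"
            )


def read_genotype_table(
    path: Union[str, Path],
    min_coverage: int = 10,
    max_stutter: float = 0.5,
) -> Dict[str, Dict[str, GenotypeCall]]:
    """Parse a (possibly multi-sample) genotype table.

    Validity is recomputed from the coverage and stutter columns under
    the given policy rather than trusted from the file.  All row-level
    errors (malformed genotype, negative coverage, stutter outside
    [0, 1]) are collected before failing.
    """
    samples: Dict[str, Dict[str, GenotypeCall]] = {}
    errors: List[str] = []
    n_rows = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_rows += 1
            fields = line.split("\t")
            if len(fields) != len(_GENOTYPE_COLUMNS):
                errors.append(
                    f"line {lineno}: expected {len(_GENOTYPE_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
                continue
            sample, _amplicon, locus_id, genotype, coverage_s, stutter_s = fields[:6]
            try:
                parse_genotype(genotype)
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            try:
                coverage = int(coverage_s)
                stutter = float(stutter_s)
            except ValueError:
                errors.append(f"line {lineno}: non-numeric coverage or stutter ratio")
                continue
            if coverage < 0:
                errors.append(f"line {lineno}: negative coverage {coverage}")
                continue
            if not 0.0 <= stutter <= 1.0:
                errors.append(f"line {lineno}: stutter ratio {stutter} outside [0, 1]")
                continue
            call = GenotypeCall(
                locus_id=locus_id,
                genotype=genotype,
                coverage=coverage,
                stutter_ratio=stutter,
            )
            call.valid = apply_validity_filter(call, min_coverage, max_stutter)
            samples.setdefault(sample, {})[locus_id] = call
    if errors:
        raise TableFormatError(str(path), errors)
    if n_rows == 0:
        logger.warning("%s: empty genotype table", path)
    return samples


# -- simulation truth -------------------------------------------------------

def write_truth_table(truth: SimTruth, path: Union[str, Path]) -> None:
    params = {"seed": truth.seed, **{k: v for k, v in asdict(truth.config).items()}}
    with open(path, "w") as handle:
        handle.write(_provenance_line(params) + "\n")
        handle.write("#locus_id\ttrue_genotype\n")
        for locus_id in sorted(truth.genotypes):
            handle.write(f"{locus_id}\t{truth.genotypes[locus_id]}\n")


def read_truth_table(path: Union[str, Path]) -> Dict[str, str]:
    genotypes: Dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            locus_id, genotype = line.split("\t")[:2]
            genotypes[locus_id] = genotype
    return genotypes


# -- analysis outputs -------------------------------------------------------

def write_diversity_table(records: Sequence[DiversityRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        handle.write(_provenance_line() + "\n")
        handle.write(
            "#locus_id\tchromosome\tposition\tdistinguishable_pairs\t"
            "total_pairs\tdiversity_index\tselected\n"
        )
        for rec in records:
            handle.write(
                "\t".join(
                    [
                        rec.locus_id,
                        rec.chromosome or _MISSING,
                        str(rec.position) if rec.position is not None else _MISSING,
                        str(rec.distinguishable_pairs),
                        str(rec.total_pairs),
                        f"{rec.diversity_index:.4f}",
                        "1" if rec.selected else "0",
                    ]
                )
                + "\n"
            )


def write_comparison_table(
    records: Sequence[ComparisonRecord],
    path: Union[str, Path],
    params: Optional[Mapping[str, object]] = None,
) -> None:
    """One row per comparable locus; differential rows are flagged '*'."""
    with open(path, "w") as handle:
        handle.write(_provenance_line(params) + "\n")
        handle.write(
            "#locus_id\tchromosome\tgenotype_a\tgenotype_b\t"
            "differential\tlength_diff_bp\tbin\n"
        )
        for rec in records:
            handle.write(
                "\t".join(
                    [
                        rec.locus_id,
                        rec.chromosome or _MISSING,
                        rec.genotype_a,
                        rec.genotype_b,
                        "*" if rec.differential else _MISSING,
                        str(rec.length_diff_bp),
                        rec.bin if rec.bin is not None else _MISSING,
                    ]
                )
                + "\n"
            )


def write_annotation_table(
    rows: Sequence[Tuple[str, Optional[str], str, str, str]],
    path: Union[str, Path],
) -> None:
    """Rows of (locus_id, gene_id, region, repeat_type, frameshift_status)."""
    with open(path, "w") as handle:
        handle.write(_provenance_line() + "\n")
        handle.write("#locus_id\tgene_id\tregion\trepeat_type\tframeshift_status\n")
        for locus_id, gene_id, region, rtype, fstatus in rows:
            handle.write(
                "\t".join([locus_id, gene_id or _MISSING, region, rtype, fstatus]) + "\n"
            )


def write_summary_json(summary: ComparisonSummary, path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        json.dump(asdict(summary), handle, indent=2, sort_keys=True)
        handle.write("\n")
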