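"""SSR genotype calling from amplicon sequencing reads.

A simple sequence repeat (SSR, microsatellite) locus is genotyped from
reads by anchoring on its flanking sequences: the last ``anchor_len``
bases of the left flank and the first ``anchor_len`` bases of the right
flank delimit the repeat tract in any read that fully spans it.  The
number of complete motif copies between the anchors is the read's allele,
written as motif + count (``AT10``).  Per-locus read tallies yield a
major-allele genotype, a PCR-stutter ratio (minor/major read counts) and
a validity flag under a coverage/stutter policy.

Two repeat tracts separated by fewer than 10 bases on one amplicon are
genotyped jointly as a compound locus with an underscore-joined genotype
string (``AAT4_AAT10``); tracts at least 10 bases apart are independent
loci.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "SSRLocus",
    "CompoundLocus",
    "AlleleTally",
    "GenotypeCall",
    "NoCallError",
    "PanelError",
    "GenotypeParseError",
    "DEFAULT_ANCHOR_LEN",
    "DEFAULT_MAX_MISMATCH",
    "DEFAULT_MIN_COVERAGE",
    "PANEL_MIN_COVERAGE",
    "DEFAULT_MAX_STUTTER",
    "MERGE_GAP_BP",
    "count_repeats",
    "reverse_complement",
    "parse_genotype",
    "genotype_length",
    "locate_and_type_read",
    "tally_alleles",
    "call_genotype",
    "apply_validity_filter",
    "merge_nearby_loci",
    "AmpliconIndex",
    "genotype_reads",
]

# Default typing and validity parameters.  Coverage counts reads
# supporting the major allele; the stutter threshold is strict (< 0.5).
DEFAULT_ANCHOR_LEN = 12
DEFAULT_MAX_MISMATCH = 1
DEFAULT_MIN_COVERAGE = 10   # per-sample validity in pairwise comparisons
PANEL_MIN_COVERAGE = 20     # stricter validity used during panel design
DEFAULT_MAX_STUTTER = 0.5
MERGE_GAP_BP = 10           # tracts closer than this merge into one locus

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

_GENOTYPE_RE = re.compile(r"^([ACGT]+?)(\d+)$")


class NoCallError(ValueError):
    """Raised when a genotype is requested for a locus with no spanning reads."""


class PanelError(ValueError):
    """Raised for inconsistent locus panels (e.g. overlapping tracts)."""


class GenotypeParseError(ValueError):
    """Raised for genotype strings that do not match the motif+count grammar."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SSRLocus:
    """One simple repeat tract on an amplicon.

    Coordinates are 1-based inclusive on the reference; ``left_flank`` /
    ``right_flank`` are the sequences immediately adjacent to the tract
    and must not end/begin with a full copy of the motif (the tract is
    maximal).
    """

    locus_id: str
    amplicon_id: str
    chromosome: str
    start: int
    end: int
    motif: str
    ref_repeat_count: int
    left_flank: str
    right_flank: str
    national_standard_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.motif or not set(self.motif) <= set("ACGT"):
            raise ValueError(f"invalid motif {self.motif!r}")
        if not 1 <= len(self.motif) <= 6:
            raise ValueError(f"motif length must be 1-6, got {self.motif!r}")
        if self.ref_repeat_count < 1:
            raise ValueError("ref_repeat_count must be positive")

    @property
    def components(self) -> Tuple["SSRLocus", ...]:
        return (self,)

    @property
    def gaps(self) -> Tuple[str, ...]:
        return ()

    @property
    def ref_length(self) -> int:
        return len(self.motif) * self.ref_repeat_count

    @property
    def ref_genotype(self) -> str:
        return f"{self.motif}{self.ref_repeat_count}"


@dataclass(frozen=True)
class CompoundLocus:
    """Two or more repeat tracts separated by sub-threshold gaps.

    Genotyped as one unit; the genotype string joins component genotypes
    with ``_``.  ``gaps`` holds the reference sequence between adjacent
    tracts (each shorter than :data:`MERGE_GAP_BP` bases).
    """

    components: Tuple[SSRLocus, ...]
    gaps: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise ValueError("a compound locus needs at least two components")
        if len(self.gaps) != len(self.components) - 1:
            raise ValueError("need exactly one gap per adjacent tract pair")
        if any(len(g) >= MERGE_GAP_BP for g in self.gaps):
            raise ValueError(f"every gap must be shorter than {MERGE_GAP_BP} bp")
        starts = [c.start for c in self.components]
        if starts != sorted(starts):
            raise ValueError("components must be sorted by start")

    @property
    def locus_id(self) -> str:
        return "+".join(c.locus_id for c in self.components)

    @property
    def amplicon_id(self) -> str:
        return self.components[0].amplicon_id

    @property
    def chromosome(self) -> str:
        return self.components[0].chromosome

    @property
    def start(self) -> int:
        return self.components[0].start

    @property
    def end(self) -> int:
        return self.components[-1].end

    @property
    def left_flank(self) -> str:
        return self.components[0].left_flank

    @property
    def right_flank(self) -> str:
        return self.components[-1].right_flank

    @property
    def national_standard_name(self) -> Optional[str]:
        for c in self.components:
            if c.national_standard_name:
                return c.national_standard_name
        return None

    @property
    def ref_length(self) -> int:
        return sum(c.ref_length for c in self.components)

    @property
    def ref_genotype(self) -> str:
        return "_".join(c.ref_genotype for c in self.components)


Locus = Union[SSRLocus, CompoundLocus]


@dataclass
class AlleleTally:
    """Read support per genotype string at one locus."""

    locus_id: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def n_spanning(self) -> int:
        return sum(self.counts.values())

    def __bool__(self) -> bool:
        return bool(self.counts)


@dataclass
class GenotypeCall:
    """Major-allele genotype of one locus in one sample.

    ``coverage`` is the number of reads supporting the major genotype
    (not total depth); ``stutter_ratio`` is the minor/major read-count
    ratio, 0 when a single allele was observed.
    """

    locus_id: str
    genotype: str
    coverage: int
    stutter_ratio: float
    valid: bool = False


# ---------------------------------------------------------------------------
# repeat counting and the genotype grammar
# ---------------------------------------------------------------------------

def count_repeats(segment: str, motif: str) -> int:
    """Number of complete, contiguous, in-register motif copies at the
    start of ``segment``.

    Counting stops at the first out-of-register base; a trailing partial
    copy is not counted.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    m = len(motif)
    n = 0
    pos = 0
    while segment.startswith(motif, pos):
        pos += m
        n += 1
    return n


def parse_genotype(genotype: str) -> List[Tuple[str, int]]:
    """Split a genotype string into (motif, count) components.

    ``"AT10"`` -> ``[("AT", 10)]``; ``"AAT4_AAT10"`` -> two components.
    """
    components = []
    for token in genotype.split("_"):
        match = _GENOTYPE_RE.match(token)
        if match is None:
            raise GenotypeParseError(
                f"malformed genotype component {token!r} in {genotype!r}"
            )
        components.append((match.group(1), int(match.group(2))))
    return components


def genotype_length(genotype: str) -> int:
    """Total tract length in bases implied by a genotype string."""
    return sum(len(motif) * count for motif, count in parse_genotype(genotype))


# ---------------------------------------------------------------------------
# flank anchoring
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _approx_positions(read: np.ndarray, anchor: np.ndarray, max_mismatch: int) -> np.ndarray:
    """Start positions where ``anchor`` matches ``read`` with at most
    ``max_mismatch`` substitutions (no indels)."""
    m = anchor.size
    if read.size < m:
        return np.empty(0, dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(read, m)
    mismatches = np.count_nonzero(windows != anchor, axis=1)
    return np.flatnonzero(mismatches <= max_mismatch)


def _anchors(locus: Locus, anchor_len: int) -> Tuple[str, str]:
    left = locus.left_flank[-anchor_len:]
    right = locus.right_flank[:anchor_len]
    if len(left) < anchor_len or len(right) < anchor_len:
        raise ValueError(
            f"flanks of locus {locus.locus_id} shorter than anchor_len={anchor_len}"
        )
    return left, right


def _type_segment(segment: str, locus: Locus) -> str:
    """Genotype string of the between-anchor segment of a spanning read."""
    parts = []
    pos = 0
    components = locus.components
    gaps = locus.gaps
    for i, comp in enumerate(components):
        k = count_repeats(segment[pos:], comp.motif)
        parts.append(f"{comp.motif}{k}")
        pos += k * len(comp.motif)
        if i < len(gaps):
            pos += len(gaps[i])
    return "_".join(parts)


def locate_and_type_read(
    read: str,
    locus: Locus,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> Optional[str]:
    """Type one read at one locus, or return ``None`` for non-spanning,
    ambiguous or unrecognisable reads.

    Both the read and its reverse complement are searched for the locus's
    left and right anchors (``anchor_len`` flank bases each, allowing up
    to ``max_mismatch`` substitutions).  The read contributes a genotype
    only when each anchor occurs exactly once and in order; reads with
    tandem-ambiguous anchor matches are discarded rather than guessed at.
    """
    if anchor_len < 6:
        raise ValueError("anchor_len must be >= 6")
    left, right = _anchors(locus, anchor_len)
    left_arr = _encode(left)
    right_arr = _encode(right)

    for oriented in (read, reverse_complement(read)):
        arr = _encode(oriented)
        lpos = _approx_positions(arr, left_arr, max_mismatch)
        if lpos.size != 1:
            continue
        rpos = _approx_positions(arr, right_arr, max_mismatch)
        if rpos.size != 1:
            continue
        seg_start = int(lpos[0]) + anchor_len
        seg_end = int(rpos[0])
        if seg_end < seg_start:  # anchors out of order or overlapping
            continue
        return _type_segment(oriented[seg_start:seg_end], locus)
    return None


def tally_alleles(
    reads: Iterable[str],
    locus: Locus,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> AlleleTally:
    """Tally genotype strings over all spanning reads of a locus."""
    counts: Counter = Counter()
    for read in reads:
        genotype = locate_and_type_read(read, locus, anchor_len, max_mismatch)
        if genotype is not None:
            counts[genotype] += 1
    return AlleleTally(locus_id=locus.locus_id, counts=dict(counts))


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

def call_genotype(tally: AlleleTally, ref_length: Optional[int] = None) -> GenotypeCall:
    """Call the major-allele genotype from a read tally.

    The allele with the most supporting reads is the genotype (inbred,
    homozygous material is assumed); the stutter ratio is the
    second-largest count divided by the largest, 0 for a single observed
    allele.  Ties for the top count are broken toward the allele whose
    implied tract length is closest to the reference length (when known),
    then lexicographically; tied calls carry stutter ratio 1.0 and can
    never pass a stutter threshold <= 1.
    """
    if not tally.counts:
        raise NoCallError(f"locus {tally.locus_id}: no spanning reads")
    top = max(tally.counts.values())
    candidates = sorted(g for g, c in tally.counts.items() if c == top)
    if len(candidates) > 1 and ref_length is not None:
        candidates.sort(key=lambda g: (abs(genotype_length(g) - ref_length), g))
    genotype = candidates[0]
    others = [c for g, c in tally.counts.items() if g != genotype]
    second = max(others) if others else 0
    return GenotypeCall(
        locus_id=tally.locus_id,
        genotype=genotype,
        coverage=top,
        stutter_ratio=second / top,
    )


def apply_validity_filter(
    call: GenotypeCall,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    max_stutter: float = DEFAULT_MAX_STUTTER,
) -> bool:
    """True iff coverage >= ``min_coverage`` and stutter < ``max_stutter``.

    Both bounds follow the screening policy: the stutter comparison is
    strict, so a locus at exactly the threshold is invalid.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if not 0 < max_stutter <= 1:
        raise ValueError("max_stutter must be in (0, 1]")
    return call.coverage >= min_coverage and call.stutter_ratio < max_stutter


# ---------------------------------------------------------------------------
# merging nearby tracts
# ---------------------------------------------------------------------------

def merge_nearby_loci(loci: Sequence[SSRLocus]) -> List[Locus]:
    """Chain tracts on one amplicon whose gaps are < 10 bp into compound
    loci; tracts >= 10 bp apart stay separate.  Merging is transitive
    along a chain of close tracts."""
    if not loci:
        return []
    amplicons = {l.amplicon_id for l in loci}
    if len(amplicons) != 1:
        raise PanelError(f"loci from multiple amplicons: {sorted(amplicons)}")
    ordered = sorted(loci, key=lambda l: l.start)
    merged: List[Locus] = []
    chain: List[SSRLocus] = [ordered[0]]
    gaps: List[str] = []

    def _flush() -> None:
        if len(chain) == 1:
            merged.append(chain[0])
        else:
            merged.append(CompoundLocus(components=tuple(chain), gaps=tuple(gaps)))

    for prev, cur in zip(ordered, ordered[1:]):
        gap = cur.start - prev.end - 1
        if gap < 0:
            raise PanelError(
                f"overlapping tracts {prev.locus_id} and {cur.locus_id} "
                f"on amplicon {prev.amplicon_id}"
            )
        if gap < MERGE_GAP_BP:
            gaps.append(prev.right_flank[:gap])
            chain.append(cur)
        else:
            _flush()
            chain = [cur]
            gaps = []
    _flush()
    return merged


# ---------------------------------------------------------------------------
# whole-sample genotyping of pooled reads
# ---------------------------------------------------------------------------

class AmpliconIndex:
    """k-mer index over locus flanks for assigning pooled reads to loci.

    Amplicon reads begin at the amplicon ends, so flank k-mers (indexed
    on both strands) identify the source locus without alignment; k-mers
    shared between loci are treated as uninformative.
    """

    def __init__(self, loci: Sequence[Locus], k: int = 16, stride: int = 5):
        self.k = k
        self.stride = stride
        self.loci = list(loci)
        index: Dict[str, Optional[int]] = {}
        for i, locus in enumerate(self.loci):
            for flank in (locus.left_flank, locus.right_flank):
                for seq in (flank, reverse_complement(flank)):
                    for off in range(0, len(seq) - k + 1):
                        kmer = seq[off : off + k]
                        if index.setdefault(kmer, i) != i:
                            index[kmer] = None  # ambiguous between loci
        self._index = index

    def assign(self, read: str) -> Optional[Locus]:
        """Locus of the first informative flank k-mer in the read, if any."""
        index = self._index
        k = self.k
        for pos in range(0, len(read) - k + 1, self.stride):
            hit = index.get(read[pos : pos + k], None)
            if hit is not None:
                return self.loci[hit]
        return None


def genotype_reads(
    reads: Iterable[str],
    panel: Sequence[SSRLocus],
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    max_stutter: float = DEFAULT_MAX_STUTTER,
) -> Tuple[Dict[str, GenotypeCall], Dict[str, AlleleTally]]:
    """Genotype every panel locus from a pool of single-end reads.

    Simple loci closer than 10 bp on one amplicon are first merged into
    compound loci; reads are assigned to loci by flank k-mers and typed
    by anchor matching.  Returns calls (with validity under the given
    policy) and the underlying tallies, both keyed by locus id; loci with
    no spanning reads are absent from the calls but present (empty) in
    the tallies.
    """
    by_amplicon: Dict[str, List[SSRLocus]] = {}
    for locus in panel:
        by_amplicon.setdefault(locus.amplicon_id, []).append(locus)
    merged: List[Locus] = []
    for amp_loci in by_amplicon.values():
        merged.extend(merge_nearby_loci(amp_loci))

    index = AmpliconIndex(merged)
    assigned: Dict[str, List[str]] = {locus.locus_id: [] for locus in merged}
    for read in reads:
        locus = index.assign(read)
        if locus is not None:
            assigned[locus.locus_id].append(read)

    calls: Dict[str, GenotypeCall] = {}
    tallies: Dict[str, AlleleTally] = {}
    for locus in merged:
        tally = tally_alleles(assigned[locus.locus_id], locus, anchor_len, max_mismatch)
        tallies[locus.locus_id] = tally
        if tally:
            call = call_genotype(tally, ref_length=locus.ref_length)
            call.valid = apply_validity_filter(call, min_coverage, max_stutter)
            calls[locus.locus_id] = call
    return calls, tallies
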