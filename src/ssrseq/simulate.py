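"""Synthetic amplicon references, SSR panels and stutter-bearing reads.

The generator builds, per locus, a random motif-free flanked repeat
tract with a known repeat count, then emits single-end reads that each
cover the whole amplicon (amplicon sequencing: no random placement).
PCR replication slippage is modelled per read: with probability
``slippage_prob`` the tract gains or loses whole motif units (loss with
probability ``contraction_prob``, step size geometric with parameter
``step_q``, truncated so at least one unit remains), after which
independent base-substitution errors are applied.  Everything is
deterministic under the configured seed, and the true genotypes are
retained so calling accuracy can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genotyping import (
    GenotypeCall,
    Locus,
    SSRLocus,
    apply_validity_filter,
    merge_nearby_loci,
    reverse_complement,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "AccuracyReport",
    "make_reference",
    "simulate_reads",
    "evaluate_accuracy",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation run.

    Defaults follow the screening regime the package targets: 300 bp
    single-end reads, per-read slippage probability 0.12 dominated by
    contractions, and a 0.005/base substitution error rate, so typical
    stutter ratios stay below the 0.5 validity threshold.
    """

    n_loci: int = 100
    motif_lengths: Tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    repeat_min: int = 4
    repeat_max: int = 20
    flank_len: int = 40
    read_length: int = 300
    depth: int = 50
    slippage_prob: float = 0.12
    contraction_prob: float = 0.8
    step_q: float = 0.3
    sub_error: float = 0.005
    compound_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("slippage_prob", "contraction_prob", "step_q",
                     "sub_error", "compound_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.repeat_min < 1 or self.repeat_max < self.repeat_min:
            raise ValueError("need 1 <= repeat_min <= repeat_max")
        if any(m < 1 or m > 6 for m in self.motif_lengths):
            raise ValueError("motif lengths must be within 1-6")
        if self.flank_len < 16:
            raise ValueError("flank_len must be >= 16 for anchoring")
        max_tract = self.repeat_max * max(self.motif_lengths)
        if self.read_length <= 2 * self.flank_len + max_tract:
            raise ValueError(
                "read_length must exceed 2*flank_len + the longest tract "
                f"({2 * self.flank_len + max_tract})"
            )


@dataclass
class SimTruth:
    """Reference, panel and true genotypes of one simulated experiment."""

    config: SimConfig
    panel: List[SSRLocus]                  # one row per simple tract
    merged: List[Locus]                    # post-merge loci, pipeline keys
    amplicons: Dict[str, str]              # amplicon_id -> reference sequence
    genotypes: Dict[str, str]              # merged locus_id -> true genotype

    @property
    def seed(self) -> int:
        return self.config.seed


def _random_motif(rng: np.random.Generator, length: int) -> str:
    """A primitive motif: not a whole-number repetition of a shorter unit."""
    while True:
        motif = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
        primitive = all(
            motif != motif[:d] * (length // d)
            for d in range(1, length)
            if length % d == 0
        )
        if primitive:
            return motif


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))


def _motif_free_left(rng: np.random.Generator, seq: str, motif: str) -> str:
    """Rewrite the end of ``seq`` until it no longer ends with ``motif``."""
    m = len(motif)
    while seq.endswith(motif):
        seq = seq[:-m] + _random_seq(rng, m)
    return seq


def _motif_free_right(rng: np.random.Generator, seq: str, motif: str) -> str:
    m = len(motif)
    while seq.startswith(motif):
        seq = _random_seq(rng, m) + seq[m:]
    return seq


def make_reference(config: SimConfig) -> SimTruth:
    """Generate amplicon references, a locus panel and true genotypes.

    A ``compound_fraction`` of amplicons carry two tracts separated by a
    gap shorter than 10 bp, exercising locus merging.  Tract borders are
    kept motif-free so every tract is maximal and the constructed repeat
    count is the truth.
    """
    rng = np.random.default_rng(config.seed)
    panel: List[SSRLocus] = []
    amplicons: Dict[str, str] = {}
    chrom = "chr1"
    spacing = 2_000
    for i in range(config.n_loci):
        amplicon_id = f"AMPL{i:06d}"
        amp_start = 1 + i * spacing
        is_compound = rng.random() < config.compound_fraction

        # Resample repeat counts until the amplicon fits in one read.
        while True:
            motifs = [_random_motif(rng, int(rng.choice(config.motif_lengths)))]
            counts = [int(rng.integers(config.repeat_min, config.repeat_max + 1))]
            gap_len = 0
            if is_compound:
                motifs.append(_random_motif(rng, int(rng.choice(config.motif_lengths))))
                counts.append(int(rng.integers(config.repeat_min, config.repeat_max + 1)))
                gap_len = int(rng.integers(1, 10))
            tract_total = sum(len(m) * c for m, c in zip(motifs, counts)) + gap_len
            if 2 * config.flank_len + tract_total <= config.read_length:
                break

        left = _motif_free_left(rng, _random_seq(rng, config.flank_len), motifs[0])
        right = _motif_free_right(rng, _random_seq(rng, config.flank_len), motifs[-1])
        gap = ""
        if is_compound:
            gap = _random_seq(rng, gap_len)
            gap = _motif_free_right(rng, gap, motifs[0])
            gap = _motif_free_left(rng, gap, motifs[1])

        tracts = [m * c for m, c in zip(motifs, counts)]
        sequence = left + tracts[0] + (gap + tracts[1] if is_compound else "") + right
        amplicons[amplicon_id] = sequence

        tract_start = amp_start + len(left)
        for j, (motif, count) in enumerate(zip(motifs, counts)):
            start = tract_start
            end = start + len(motif) * count - 1
            left_flank = sequence[: start - amp_start]
            right_flank = sequence[end - amp_start + 1 :]
            panel.append(
                SSRLocus(
                    locus_id=f"SSR{i:06d}" + ("" if not is_compound else "ab"[j]),
                    amplicon_id=amplicon_id,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    motif=motif,
                    ref_repeat_count=count,
                    left_flank=left_flank,
                    right_flank=right_flank,
                )
            )
            tract_start = end + 1 + gap_len

    by_amplicon: Dict[str, List[SSRLocus]] = {}
    for locus in panel:
        by_amplicon.setdefault(locus.amplicon_id, []).append(locus)
    merged: List[Locus] = []
    for amp_loci in by_amplicon.values():
        merged.extend(merge_nearby_loci(amp_loci))
    merged.sort(key=lambda l: l.start)
    genotypes = {locus.locus_id: locus.ref_genotype for locus in merged}
    return SimTruth(
        config=config,
        panel=panel,
        merged=merged,
        amplicons=amplicons,
        genotypes=genotypes,
    )


def _apply_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n_err = rng.binomial(arr.size, rate)
    if n_err == 0:
        return seq
    positions = rng.choice(arr.size, size=n_err, replace=False)
    for pos in positions:
        current = arr[pos]
        choices = _BASES[_BASES != current]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_reads(truth: SimTruth, config: Optional[SimConfig] = None) -> List[Tuple[str, str]]:
    """Emit ``depth`` stutter- and error-bearing reads per locus.

    Returns ``(read_id, sequence)`` pairs; read order and content are
    deterministic under the config seed.  Reads are reverse-complemented
    with probability 1/2 (random sequencing strand) and truncated to the
    configured read length when an expansion overruns it.
    """
    config = config or truth.config
    rng = np.random.default_rng((config.seed * 2_654_435_761 + 97) % 2**31)
    reads: List[Tuple[str, str]] = []
    for locus in truth.merged:
        components = locus.components
        gaps = locus.gaps
        true_counts = [c.ref_repeat_count for c in components]
        left = locus.left_flank
        right = locus.right_flank

        slips = rng.random(config.depth) < config.slippage_prob
        which = rng.integers(0, len(components), size=config.depth)
        contract = rng.random(config.depth) < config.contraction_prob
        steps = rng.geometric(config.step_q, size=config.depth)
        flip = rng.random(config.depth) < 0.5

        for j in range(config.depth):
            counts = list(true_counts)
            if slips[j]:
                idx = int(which[j])
                step = int(steps[j])
                if contract[j]:
                    counts[idx] = max(1, counts[idx] - step)
                else:
                    counts[idx] = counts[idx] + step
            middle = components[0].motif * counts[0]
            for g, comp, c in zip(gaps, components[1:], counts[1:]):
                middle += g + comp.motif * c
            seq = left + middle + right
            seq = _apply_substitutions(rng, seq, config.sub_error)
            if flip[j]:
                seq = reverse_complement(seq)
            if len(seq) > config.read_length:
                seq = seq[: config.read_length]
            reads.append((f"{locus.amplicon_id}_r{j}", seq))
    return reads


@dataclass
class AccuracyReport:
    accuracy: float
    n_correct: int
    n_evaluated: int            # calls passing the policy
    n_no_call: int              # loci with no spanning reads
    n_filtered: int             # called but failing the policy
    per_locus: List[Tuple[str, str, Optional[str], str]] = field(default_factory=list)
    # (locus_id, truth, called genotype or None, status)


def evaluate_accuracy(
    calls: Dict[str, GenotypeCall],
    truth: SimTruth,
    min_coverage: int = 1,
    max_stutter: float = 0.5,
) -> AccuracyReport:
    """Fraction of policy-passing calls whose genotype equals the truth.

    Loci with no spanning reads are excluded from the denominator and
    reported separately, as are calls failing the coverage/stutter
    policy.
    """
    n_correct = 0
    n_evaluated = 0
    n_no_call = 0
    n_filtered = 0
    per_locus = []
    for locus_id, true_genotype in truth.genotypes.items():
        call = calls.get(locus_id)
        if call is None:
            n_no_call += 1
            per_locus.append((locus_id, true_genotype, None, "no_call"))
            continue
        if not apply_validity_filter(call, min_coverage, max_stutter):
            n_filtered += 1
            per_locus.append((locus_id, true_genotype, call.genotype, "filtered"))
            continue
        n_evaluated += 1
        correct = call.genotype == true_genotype
        n_correct += correct
        per_locus.append(
            (locus_id, true_genotype, call.genotype, "correct" if correct else "wrong")
        )
    if n_evaluated == 0:
        raise ValueError("no calls pass the policy; accuracy undefined")
    return AccuracyReport(
        accuracy=n_correct / n_evaluated,
        n_correct=n_correct,
        n_evaluated=n_evaluated,
        n_no_call=n_no_call,
        n_filtered=n_filtered,
        per_locus=per_locus,
    )
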