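"""Unit and property tests for repeat counting, read typing and calling."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrseq import (
    AlleleTally,
    CompoundLocus,
    NoCallError,
    PanelError,
    apply_validity_filter,
    call_genotype,
    count_repeats,
    genotype_length,
    locate_and_type_read,
    merge_nearby_loci,
    parse_genotype,
    reverse_complement,
    tally_alleles,
)

from conftest import LEFT_FLANK, RIGHT_FLANK, make_locus

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)
motifs = st.text(alphabet="ACGT", min_size=1, max_size=6)


# -- count_repeats ----------------------------------------------------------

@pytest.mark.parametrize(
    "segment,motif,expected",
    [
        ("AT" * 10, "AT", 10),
        ("AATAATAATAAT", "AAT", 4),       # the AAT4 component of AAT4_AAT10
        ("ATATA", "AT", 2),               # trailing partial copy ignored
        ("", "AT", 0),
        ("GGATAT", "AT", 0),              # must start in register
        ("ATATCGATAT", "AT", 2),          # stops at first interruption
    ],
)
def test_count_repeats_examples(segment, motif, expected):
    assert count_repeats(segment, motif) == expected


def test_count_repeats_rejects_empty_motif():
    with pytest.raises(ValueError):
        count_repeats("ACGT", "")


def _count_repeats_oracle(segment, motif):
    """Exhaustive oracle: largest k with motif*k a prefix of segment."""
    k = 0
    while segment.startswith(motif * (k + 1)):
        k += 1
    return k


def test_count_repeats_matches_exhaustive_oracle():
    rng = random.Random(20240917)
    for _ in range(1000):
        motif = "".join(rng.choices("ACGT", k=rng.randint(1, 6)))
        # Bias segments toward actual repeat content so non-zero counts occur.
        segment = motif * rng.randint(0, 8) + "".join(
            rng.choices("ACGT", k=rng.randint(0, 12))
        )
        assert count_repeats(segment, motif) == _count_repeats_oracle(segment, motif)


# -- genotype grammar -------------------------------------------------------

def test_parse_genotype_components():
    assert parse_genotype("AT10") == [("AT", 10)]
    assert parse_genotype("AAT4_AAT10") == [("AAT", 4), ("AAT", 10)]


@pytest.mark.parametrize("bad", ["", "10", "AT", "AXT4", "AT4_", "at10"])
def test_parse_genotype_rejects_malformed(bad):
    with pytest.raises(ValueError):
        parse_genotype(bad)


def test_genotype_length():
    assert genotype_length("AT10") == 20
    assert genotype_length("AAT4_AAT10") == 42


# -- locate_and_type_read ---------------------------------------------------

def test_typing_exact_read(at10_locus):
    read = LEFT_FLANK + "AT" * 12 + RIGHT_FLANK
    assert locate_and_type_read(read, at10_locus) == "AT12"


def test_typing_missing_right_anchor(at10_locus):
    read = LEFT_FLANK + "AT" * 12  # non-spanning read
    assert locate_and_type_read(read, at10_locus) is None


def test_typing_tolerates_one_anchor_mismatch(at10_locus):
    flank = list(LEFT_FLANK)
    flank[-2] = "A" if flank[-2] != "A" else "G"  # one substitution in the anchor
    read = "".join(flank) + "AT" * 7 + RIGHT_FLANK
    assert locate_and_type_read(read, at10_locus) == "AT7"


def test_typing_strand_symmetry(at10_locus):
    read = LEFT_FLANK + "AT" * 9 + RIGHT_FLANK
    forward = locate_and_type_read(read, at10_locus)
    reverse = locate_and_type_read(reverse_complement(read), at10_locus)
    assert forward == reverse == "AT9"


def test_typing_compound_locus():
    first = make_locus(motif="AAT", count=4, locus_id="La", start=1041)
    gap = "GTCCGAG"  # 7 bp, below the merge threshold
    second = make_locus(
        motif="AAT",
        count=10,
        locus_id="Lb",
        start=first.end + 1 + len(gap),
        left_flank=LEFT_FLANK + "AAT" * 4 + gap,
        right_flank=RIGHT_FLANK,
    )
    compound = CompoundLocus(components=(first, second), gaps=(gap,))
    read = LEFT_FLANK + "AAT" * 4 + gap + "AAT" * 10 + RIGHT_FLANK
    assert locate_and_type_read(read, compound) == "AAT4_AAT10"


@settings(derandomize=True, max_examples=60)
@given(count=st.integers(min_value=0, max_value=30))
def test_round_trip_error_free_read(count):
    """flank + motif*k + flank always types back to motif+k exactly."""
    locus = make_locus(motif="GCA", count=max(count, 1))
    read = LEFT_FLANK + "GCA" * count + RIGHT_FLANK
    assert locate_and_type_read(read, locus) == f"GCA{count}"


@settings(derandomize=True, max_examples=60)
@given(count=st.integers(min_value=1, max_value=25), flip=st.booleans())
def test_strand_symmetry_property(count, flip):
    locus = make_locus(motif="TG", count=10)
    read = LEFT_FLANK + "TG" * count + RIGHT_FLANK
    oriented = reverse_complement(read) if flip else read
    assert locate_and_type_read(oriented, locus) == f"TG{count}"


# -- tally and call ---------------------------------------------------------

def test_tally_alleles_counts(at10_locus):
    reads = [LEFT_FLANK + "AT" * 10 + RIGHT_FLANK] * 80
    reads += [LEFT_FLANK + "AT" * 9 + RIGHT_FLANK] * 20
    tally = tally_alleles(reads, at10_locus)
    assert tally.counts == {"AT10": 80, "AT9": 20}
    assert tally.n_spanning == 100


def test_tally_empty_for_no_spanning_reads(at10_locus):
    tally = tally_alleles(["ACGT" * 20], at10_locus)
    assert not tally
    assert tally.n_spanning == 0


def test_call_genotype_major_and_stutter():
    call = call_genotype(AlleleTally("L1", {"AT10": 100, "AT9": 30}))
    assert call.genotype == "AT10"
    assert call.coverage == 100
    assert call.stutter_ratio == pytest.approx(0.30)


def test_call_genotype_single_allele_zero_stutter():
    # Schema cross-check mirroring a single-dominant-allele table row.
    call = call_genotype(AlleleTally("L1", {"GAA15": 1192}))
    assert call.genotype == "GAA15"
    assert call.coverage == 1192
    assert call.stutter_ratio == 0.0


def test_call_genotype_tie_is_invalid_and_deterministic():
    call = call_genotype(AlleleTally("L1", {"AT10": 50, "AT9": 50}), ref_length=20)
    assert call.stutter_ratio == 1.0
    assert call.genotype == "AT10"  # closer to the reference length
    assert not apply_validity_filter(call, min_coverage=10, max_stutter=1.0)


def test_call_genotype_empty_tally_raises():
    with pytest.raises(NoCallError):
        call_genotype(AlleleTally("L1", {}))


def test_stutter_ratio_bounds_property():
    rng = random.Random(7)
    for _ in range(200):
        counts = {
            f"AT{k}": rng.randint(1, 500)
            for k in rng.sample(range(3, 30), rng.randint(1, 6))
        }
        tally = AlleleTally("L", counts)
        call = call_genotype(tally)
        assert 0.0 <= call.stutter_ratio <= 1.0
        assert (call.stutter_ratio == 0.0) == (len(counts) == 1)
        assert call.coverage == max(counts.values())
        assert tally.n_spanning == sum(counts.values())


# -- validity filter --------------------------------------------------------

@pytest.mark.parametrize(
    "coverage,stutter,min_cov,max_stutter,expected",
    [
        (9, 0.1, 10, 0.5, False),     # below read threshold
        (100, 0.50, 10, 0.5, False),  # stutter bound is strict
        (47, 0.13, 10, 0.5, True),    # a passing national-standard row
        (19, 0.32, 10, 0.5, True),
        (20, 0.49, 20, 0.5, True),
        (19, 0.1, 20, 0.5, False),    # panel-design policy is stricter
    ],
)
def test_validity_filter(coverage, stutter, min_cov, max_stutter, expected):
    from ssrseq import GenotypeCall

    call = GenotypeCall("L", "AT10", coverage, stutter)
    assert apply_validity_filter(call, min_cov, max_stutter) is expected


# -- merging nearby tracts --------------------------------------------------

def _simple(start, end, locus_id, right_flank="GCTTAAGGCCTA"):
    motif = "AT"
    count = (end - start + 1) // 2
    return make_locus(
        motif=motif, count=count, locus_id=locus_id, start=start,
        right_flank=right_flank,
    )


def test_merge_below_threshold():
    a = _simple(100, 111, "A")        # ends at 111
    b = _simple(119, 130, "B")        # gap of 7 < 10 -> merge
    merged = merge_nearby_loci([a, b])
    assert len(merged) == 1
    assert isinstance(merged[0], CompoundLocus)
    assert merged[0].gaps == (a.right_flank[:7],)


def test_gap_of_exactly_ten_stays_separate():
    a = _simple(100, 111, "A")
    b = _simple(122, 133, "B")        # gap of 10 -> two loci
    merged = merge_nearby_loci([a, b])
    assert len(merged) == 2


def test_merge_transitive_chain_matches_interval_oracle():
    rng = random.Random(11)
    for _ in range(100):
        # Random non-overlapping tracts along one amplicon.
        loci, pos = [], 50
        for i in range(rng.randint(1, 6)):
            length = 2 * rng.randint(2, 8)
            loci.append(_simple(pos, pos + length - 1, f"L{i}"))
            pos += length + rng.randint(1, 25)
        shuffled = loci[:]
        rng.shuffle(shuffled)
        merged = merge_nearby_loci(shuffled)

        # Brute-force interval chaining oracle.
        expected_groups, group = [], [loci[0]]
        for prev, cur in zip(loci, loci[1:]):
            if cur.start - prev.end - 1 < 10:
                group.append(cur)
            else:
                expected_groups.append(group)
                group = [cur]
        expected_groups.append(group)

        assert [tuple(c.locus_id for c in m.components) for m in merged] == [
            tuple(l.locus_id for l in g) for g in expected_groups
        ]
        for m in merged:
            # One underscore per gap in the reference genotype string.
            assert m.ref_genotype.count("_") == len(m.components) - 1


def test_merge_rejects_overlapping_tracts():
    a = _simple(100, 111, "A")
    b = _simple(110, 121, "B")
    with pytest.raises(PanelError):
        merge_nearby_loci([a, b])
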