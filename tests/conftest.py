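import pytest

from ssrseq import SSRLocus

# Fixed, motif-free flanking sequences used across locus fixtures.
LEFT_FLANK = "GATCCTAGGAACTGCAACGGTCCAGTTAGCATCGAGTTCG"
RIGHT_FLANK = "CTTGACCGGATCAATGGCTTAGCCGATACCAGTTGGCAAC"


def make_locus(
    motif="AT",
    count=10,
    locus_id="L1",
    amplicon_id="AMP1",
    chromosome="chr1",
    start=1041,
    left_flank=LEFT_FLANK,
    right_flank=RIGHT_FLANK,
    national_standard_name=None,
):
    return SSRLocus(
        locus_id=locus_id,
        amplicon_id=amplicon_id,
        chromosome=chromosome,
        start=start,
        end=start + len(motif) * count - 1,
        motif=motif,
        ref_repeat_count=count,
        left_flank=left_flank,
        right_flank=right_flank,
        national_standard_name=national_standard_name,
    )


@pytest.fixture
def at10_locus():
    return make_locus()


@pytest.fixture
def locus_factory():
    return make_locus
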