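import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duplexfid import ErrorModel, revcomp, simulate_molecule
from duplexfid.align import (
    AlignedStrand,
    Scoring,
    align_semiglobal,
    align_to_reference,
    apply_read_filters,
    left_align_indels,
    read_sam,
    write_sam,
)
from duplexfid.consensus import StrandRead
from conftest import perfect_read
from oracles import bruteforce_overlap_score


def test_exact_read_aligns_as_single_match_run(amplicon):
    a = align_to_reference(perfect_read(amplicon.sequence, "second"), amplicon)
    assert a.oplist == [("match", len(amplicon.sequence))]
    assert (a.ref_start, a.ref_end) == (0, len(amplicon.sequence))
    assert a.mapping_quality == Scoring.MAPQ_SENTINEL


def test_deletion_in_homopolymer_run_is_left_aligned():
    ref = "ACTTGGGGACTTACCATTGACTA"
    read = ref[:5] + ref[6:]  # remove one G from the GGGG run
    score, cols, rs, re_ = align_semiglobal(read, ref)
    cols = left_align_indels(cols, read, ref, rs)
    assert "".join(cols) == "MMMMDMMMMMMMMMMMMMMMMMM"  # D at the first G
    assert score == bruteforce_overlap_score(read, ref)


def test_insertion_in_repeat_is_left_aligned():
    ref = "ACCAGCTGCTGCTTACCAGTTACG"
    read = ref[:4] + "GCT" + ref[4:]  # one extra GCT unit
    score, cols, rs, re_ = align_semiglobal(read, ref)
    cols = left_align_indels(cols, read, ref, rs)
    first_ins = "".join(cols).index("I")
    assert "".join(cols)[first_ins : first_ins + 3] == "III"
    assert first_ins == 4  # leftmost placement, at the start of the repeat


def test_first_strand_read_matches_second_strand_alignment(amplicon, zero_model):
    m = ErrorModel.uniform(3e-3, 3e-4, 3e-4)
    sim = simulate_molecule(amplicon, m, m, zero_model, seed=5)
    a1 = align_to_reference(perfect_read(sim.first_strand, "first"), amplicon)
    a2 = align_to_reference(perfect_read(sim.second_strand, "second"), amplicon)
    assert a1.orientation == "reverse-complemented"
    assert a1.oplist == a2.oplist  # same molecule, same edits vs reference


def test_internal_aligner_matches_bruteforce_optimum():
    """On 200 random small instances with injected indels, the production DP
    reaches the exhaustive-enumeration optimum (free terminal gaps, affine)."""
    rng = np.random.default_rng(42)
    for trial in range(200):
        n = int(rng.integers(8, 31))
        ref = "".join(rng.choice(list("ACGT"), n))
        read = list(ref)
        for _ in range(int(rng.integers(0, 4))):
            kind = rng.integers(3)
            pos = int(rng.integers(len(read)))
            if kind == 0:
                read[pos] = "ACGT"[int(rng.integers(4))]
            elif kind == 1 and len(read) > 4:
                del read[pos]
            else:
                read.insert(pos, "ACGT"[int(rng.integers(4))])
        read = "".join(read)
        score, cols, rs, re_ = align_semiglobal(read, ref)
        assert score == bruteforce_overlap_score(read, ref), (read, ref)


@given(st.integers(0, 10_000))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_aligned_strand_op_sums_are_consistent(seed):
    """Reference- and read-consuming op lengths always reconcile with the
    reference span and read length (validated in the constructor)."""
    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list("ACGT"), 60))
    from duplexfid.refgen import Amplicon

    amp = Amplicon("t", ref * 3, (0, 20), (160, 180))
    read = list(amp.sequence)
    for _ in range(int(rng.integers(0, 6))):
        pos = int(rng.integers(30, 150))
        k = rng.integers(3)
        if k == 0:
            read[pos] = "ACGT"[int(rng.integers(4))]
        elif k == 1:
            del read[pos]
        else:
            read.insert(pos, "ACGT"[int(rng.integers(4))])
    a = align_to_reference(perfect_read("".join(read), "second"), amp)
    assert isinstance(a, AlignedStrand)  # __post_init__ checks both sums


def _stub(amplicon, mapq=60, ref_start=0, ref_end=None, supplementary=0, length=None):
    L = len(amplicon.sequence)
    ref_end = L if ref_end is None else ref_end
    length = ref_end - ref_start if length is None else length
    span = ref_end - ref_start
    ops = []
    if length >= span:
        ops = [("match", span)] + ([("insertion", length - span)] if length > span else [])
    else:
        ops = [("match", length), ("deletion", span - length)]
    read = StrandRead("m", "second", "A" * length, np.full(length, 93), 15)
    return AlignedStrand(
        read=read, sequence="A" * length, qualities=np.full(length, 93),
        oplist=ops, ref_start=ref_start, ref_end=ref_end,
        mapping_quality=mapq, orientation="as-is", supplementary_count=supplementary,
    )


class TestReadFilterBoundaries:
    """The quoted filter cascade: MAPQ >= 60, span both primer regions,
    no split mapping, length within +/-50 of expected; boundaries inclusive."""

    def test_mapq_59_rejected_60_accepted(self, amplicon):
        assert apply_read_filters(_stub(amplicon, mapq=59), amplicon).reason == "mapq"
        assert apply_read_filters(_stub(amplicon, mapq=60), amplicon).accepted

    def test_alignment_must_start_in_5prime_primer(self, amplicon):
        ok = _stub(amplicon, ref_start=19)
        assert apply_read_filters(ok, amplicon, expected_len=len(ok.sequence)).accepted
        bad = _stub(amplicon, ref_start=20)
        assert apply_read_filters(bad, amplicon, expected_len=len(bad.sequence)).reason == "span_5prime"

    def test_alignment_must_end_in_3prime_primer(self, amplicon):
        L = len(amplicon.sequence)
        ok = _stub(amplicon, ref_end=amplicon.primer3[0] + 1)
        assert apply_read_filters(ok, amplicon, expected_len=len(ok.sequence)).accepted
        bad = _stub(amplicon, ref_end=amplicon.primer3[0])
        assert apply_read_filters(bad, amplicon, expected_len=len(bad.sequence)).reason == "span_3prime"

    def test_supplementary_mapping_is_chimeric(self, amplicon):
        assert apply_read_filters(_stub(amplicon, supplementary=1), amplicon).reason == "chimera"

    def test_length_deviation_50_kept_51_rejected(self, amplicon):
        L = len(amplicon.sequence)
        assert apply_read_filters(_stub(amplicon, length=L + 50), amplicon).accepted
        assert apply_read_filters(_stub(amplicon, length=L + 51), amplicon).reason == "length"
        assert apply_read_filters(_stub(amplicon, length=L - 51), amplicon).reason == "length"

    def test_outcome_independent_of_rule_order(self, amplicon):
        """A read failing several rules is rejected regardless of which rule
        fires; the recorded reason follows the fixed cascade order."""
        multi = _stub(amplicon, mapq=10, supplementary=2, length=len(amplicon.sequence) + 99)
        dec = apply_read_filters(multi, amplicon)
        assert not dec.accepted and dec.reason == "mapq"


def test_sam_roundtrip(tmp_path, amplicon, zero_model):
    m = ErrorModel.uniform(3e-3, 3e-4, 3e-4)
    sim = simulate_molecule(amplicon, m, m, m, seed=9)
    alns = [
        align_to_reference(perfect_read(sim.first_strand, "first", "molX"), amplicon),
        align_to_reference(perfect_read(sim.second_strand, "second", "molX"), amplicon),
    ]
    path = tmp_path / "aln.sam"
    write_sam(alns, amplicon, path)
    back = read_sam(path, amplicon)
    assert len(back) == 2
    for orig, rd in zip(alns, back):
        assert rd.oplist == orig.oplist
        assert (rd.ref_start, rd.ref_end) == (orig.ref_start, orig.ref_end)
        assert rd.mapping_quality == orig.mapping_quality
        assert rd.orientation == orig.orientation
        assert rd.read.strand == orig.read.strand
        assert rd.read.n_passes == orig.read.n_passes
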