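import numpy as np
import pytest

from duplexfid import (
    ErrorModel,
    call_duplex,
    call_first_strand_errors,
    call_second_strand_errors,
    classify_substitution,
    collapse_indels,
    insert_repeat,
    revcomp,
    simulate_molecule,
)
from duplexfid.errorcall import GapRecord, NotAnError
from duplexfid.refgen import Amplicon, complement
from duplexfid.align import align_to_reference
from conftest import aligned_pair, perfect_read
from oracles import enumerate_substitution_classes


class TestSubstitutionClassification:
    def test_worked_example_ref_A_cdna_C(self):
        """Reference A observed as C in the cDNA is rA->rG / dT->dC."""
        assert classify_substitution("A", "C") == ("rA->rG", "dT->dC")

    def test_all_twelve_mismatches_match_enumeration(self):
        table = enumerate_substitution_classes()
        assert len(table) == 12
        for (ref, cdna), expected in table.items():
            assert classify_substitution(ref, cdna) == expected

    def test_complement_identity_holds_for_every_mismatch(self):
        """The RNAP product base is the complement of the RT product base, and
        the RT template base the complement of the RNAP template base."""
        dna = {"A": "A", "C": "C", "G": "G", "U": "T"}
        for ref in "ACGT":
            for cdna in "ACGT":
                if cdna == complement(ref):
                    continue
                rnap, rt = classify_substitution(ref, cdna)
                rnap_from, rnap_to = rnap[1], rnap[5]
                rt_from, rt_to = rt[1], rt[5]
                assert dna[rnap_to] == complement(rt_to)
                assert rt_from == complement(dna[rnap_from])

    def test_match_is_not_an_error(self):
        with pytest.raises(NotAnError):
            classify_substitution("G", "C")
        with pytest.raises(ValueError):
            classify_substitution("N", "A")


def _mini_amplicon():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), 120))
    return Amplicon("mini", seq, (0, 10), (110, 120))


def _pair_from_ref_frame(amp, first_ref_frame, second_seq, qual_first=93, qual_second=93):
    f = perfect_read(revcomp(first_ref_frame), "first")
    s = perfect_read(second_seq, "second")
    f.qualities[:] = qual_first
    s.qualities[:] = qual_second
    return align_to_reference(f, amp), align_to_reference(s, amp)


class TestDuplexAttribution:
    """Case enumeration of the duplex confirmation rules at one locus."""

    def setup_method(self):
        self.amp = _mini_amplicon()
        self.pos = 50
        self.ref = self.amp.sequence
        self.alt = "G" if self.ref[50] != "G" else "C"

    def _mutate(self, seq, base):
        return seq[: self.pos] + base + seq[self.pos + 1 :]

    def test_confirmed_first_strand_substitution(self):
        mut = self._mutate(self.ref, self.alt)
        a1, a2 = _pair_from_ref_frame(self.amp, mut, mut)
        calls = call_duplex(a1, a2, self.amp)
        (e,) = calls.first_events
        assert (e.type, e.ref_pos, e.expected, e.observed) == ("substitution", 50, self.ref[50], self.alt)
        assert e.rnap_pair and e.rt_pair
        exp_rnap, exp_rt = classify_substitution(self.ref[50], complement(self.alt))
        assert (e.rnap_pair, e.rt_pair) == (exp_rnap, exp_rt)
        assert not calls.second_events and calls.discordant == 0

    def test_unconfirmed_first_strand_discrepancy_is_dropped(self):
        a1, a2 = _pair_from_ref_frame(self.amp, self._mutate(self.ref, self.alt), self.ref)
        calls = call_duplex(a1, a2, self.amp)
        assert not calls.first_events and not calls.second_events
        assert calls.unconfirmed_first == 1

    def test_second_strand_only_substitution(self):
        a1, a2 = _pair_from_ref_frame(self.amp, self.ref, self._mutate(self.ref, self.alt))
        calls = call_duplex(a1, a2, self.amp)
        (e,) = calls.second_events
        assert (e.type, e.ref_pos, e.observed) == ("substitution", 50, self.alt)
        assert e.rt_pair == f"d{self.ref[50]}->d{self.alt}"
        assert e.rnap_pair is None
        assert not calls.first_events

    def test_discordant_locus_counted_in_neither_class(self):
        other = next(b for b in "ACGT" if b not in (self.ref[50], self.alt))
        a1, a2 = _pair_from_ref_frame(
            self.amp, self._mutate(self.ref, self.alt), self._mutate(self.ref, other)
        )
        calls = call_duplex(a1, a2, self.amp)
        assert not calls.first_events and not calls.second_events
        assert calls.discordant == 1

    def test_primer_region_discrepancies_are_ignored(self):
        mut = self.ref[:5] + ("A" if self.ref[5] != "A" else "C") + self.ref[6:]
        a1, a2 = _pair_from_ref_frame(self.amp, mut, mut)
        calls = call_duplex(a1, a2, self.amp)
        assert not calls.first_events and not calls.second_events

    def test_qual_threshold_gates_substitutions(self):
        mut = self._mutate(self.ref, self.alt)
        a1, a2 = _pair_from_ref_frame(self.amp, mut, mut, qual_second=92)
        assert not call_duplex(a1, a2, self.amp, qual_threshold=93).first_events
        assert call_duplex(a1, a2, self.amp, qual_threshold=92).first_events

    def test_wrapper_functions_split_the_classes(self):
        mut = self._mutate(self.ref, self.alt)
        a1, a2 = _pair_from_ref_frame(self.amp, self.ref, mut)
        assert call_first_strand_errors(a1, a2, self.amp) == []
        assert len(call_second_strand_errors(a1, a2, self.amp)) == 1


class TestIndelEvents:
    def setup_method(self):
        self.amp = _mini_amplicon()
        self.ref = self.amp.sequence

    def test_multibase_deletion_is_one_event(self):
        mut = self.ref[:50] + self.ref[53:]
        a1, a2 = _pair_from_ref_frame(self.amp, mut, mut)
        calls = call_duplex(a1, a2, self.amp)
        (e,) = calls.first_events
        assert e.type == "deletion" and e.length == 3
        assert not calls.second_events

    def test_second_strand_only_deletion(self):
        mut = self.ref[:50] + self.ref[51:]
        a1, a2 = _pair_from_ref_frame(self.amp, self.ref, mut)
        calls = call_duplex(a1, a2, self.amp)
        (e,) = calls.second_events
        assert e.type == "deletion" and e.length == 1
        assert not calls.first_events

    def test_confirmed_insertion_is_one_event(self):
        mut = self.ref[:60] + "TAG" + self.ref[60:]
        a1, a2 = _pair_from_ref_frame(self.amp, mut, mut)
        calls = call_duplex(a1, a2, self.amp)
        (e,) = calls.first_events
        assert e.type == "insertion" and e.length == 3

    def test_collapse_two_separated_deletions(self):
        gaps = [
            GapRecord(10, "deletion", "A", 93),
            GapRecord(11, "deletion", "C", 93),
            GapRecord(13, "deletion", "G", 93),
        ]
        events = collapse_indels(gaps)
        assert [(e.type, e.ref_pos, e.length) for e in events] == [
            ("deletion", 10, 2),
            ("deletion", 13, 1),
        ]

    def test_collapse_insertion_records_share_anchor(self):
        gaps = [
            GapRecord(20, "insertion", "G", 93),
            GapRecord(20, "insertion", "C", 90),
            GapRecord(20, "insertion", "T", 93),
        ]
        (e,) = collapse_indels(gaps)
        assert (e.type, e.ref_pos, e.observed, e.length, e.event_qual) == (
            "insertion", 20, "GCT", 3, 90,
        )


def test_partition_of_discrepant_loci(amplicon, zero_model):
    """Every duplex locus with any discrepancy lands in exactly one of
    {first-strand, second-strand, unconfirmed, discordant}."""
    m = ErrorModel.uniform(4e-3, 4e-4, 4e-4)
    total_checked = 0
    for seed in range(30):
        sim = simulate_molecule(amplicon, m, m, m, seed=seed)
        a1, a2 = aligned_pair(sim, amplicon)
        calls = call_duplex(a1, a2, amplicon)
        # recount discrepancies independently, position by position
        from duplexfid.errorcall import project

        p1, p2 = project(a1), project(a2)
        a0, a1_ = amplicon.analyzable
        lo = max(p1.ref_start, p2.ref_start, a0)
        hi = min(p1.ref_end, p2.ref_end, a1_)
        sub_loci = sum(
            1
            for pos in range(lo, hi)
            if "-" not in (p1.at(pos)[0], p2.at(pos)[0])
            and (p1.at(pos)[0] != amplicon.sequence[pos] or p2.at(pos)[0] != amplicon.sequence[pos])
        )
        sub_events = (
            sum(1 for e in calls.first_events if e.type == "substitution")
            + sum(1 for e in calls.second_events if e.type == "substitution")
        )
        # indel loci are exercised via the truth-match tests; here the
        # substitution partition must be exact
        assert sub_loci == sub_events + calls.discordant + calls.unconfirmed_first
        total_checked += sub_loci
    assert total_checked > 30


def test_attribution_soundness_with_stage_pure_injections(amplicon, zero_model):
    """With errors injected in a single stage, calls appear only in the
    matching class and recover every analyzable truth event."""
    m = ErrorModel.uniform(3e-3, 3e-4, 3e-4)
    for stage, models in {
        "RNAP": (m, zero_model, zero_model),
        "RT1": (zero_model, m, zero_model),
        "RT2": (zero_model, zero_model, m),
    }.items():
        for seed in range(10):
            sim = simulate_molecule(amplicon, *models, seed=seed)
            calls = call_duplex(*aligned_pair(sim, amplicon), amplicon)
            expected_class = calls.first_events if stage in ("RNAP", "RT1") else calls.second_events
            other_class = calls.second_events if stage in ("RNAP", "RT1") else calls.first_events
            truth = sorted((e.type, e.ref_pos, e.length) for e in sim.truth.events)
            got = sorted((e.type, e.ref_pos, e.length) for e in expected_class)
            assert truth == got
            assert other_class == [] and calls.discordant == 0
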