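"""Duplex error extraction, strand attribution and substitution equivalence.

A first-strand (cDNA) discrepancy against the reference is counted only when
the second strand carries the identical non-reference base or indel at the
same left-aligned position — duplex confirmation, which removes consensus and
sequencing artifacts.  Loci where the second strand differs from the first
while the first matches the reference are second-strand (reverse-transcriptase
on DNA template) errors.  Loci where both strands differ from the reference
discordantly are dropped from both classes and logged, so every discrepant
locus lands in exactly one of {first, second, unconfirmed, discordant}.

An observed cDNA mismatch is compatible with two indistinguishable
misincorporation scenarios, an RNA-polymerase error or a reverse-transcriptase
error; both equivalence labels are attached to every first-strand
substitution (e.g. reference A with C in the cDNA is rA->rG / dT->dC).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import AlignedStrand
from .refgen import Amplicon, complement

_RNA = str.maketrans("ACGT", "ACGU")


class NotAnError(ValueError):
    """Raised when the observed base is the complement of the template (a match)."""


def classify_substitution(ref_base: str, cdna_base: str) -> tuple[str, str]:
    """Dual equivalence labels for an observed cDNA mismatch.

    *ref_base* is the reference (RNA-sense) base, *cdna_base* the base
    observed in the cDNA strand (cDNA frame).  Returns
    ``(rnap_pair, rt_pair)`` such as ``("rA->rG", "dT->dC")``: the RNA
    polymerase error and the reverse transcriptase error that would each
    produce this mismatch.  RNA-side bases are rendered with U.
    """
    for b, name in ((ref_base, "ref_base"), (cdna_base, "cdna_base")):
        if b not in "ACGT":
            raise ValueError(f"{name} must be one of ACGT, got {b!r}")
    if cdna_base == complement(ref_base):
        raise NotAnError(f"{cdna_base} is the complement of {ref_base}: not an error")
    rnap = f"r{ref_base.translate(_RNA)}->r{complement(cdna_base).translate(_RNA)}"
    rt = f"d{complement(ref_base)}->d{cdna_base}"
    return rnap, rt


@dataclass(frozen=True)
class ErrorEvent:
    """One attributed replication error in reference coordinates."""

    molecule_id: str
    strand: str  # attribution: "first" | "second"
    type: str  # substitution | deletion | insertion
    ref_pos: int  # 0-based; insertions: position of the following reference base
    expected: str  # reference-frame
    observed: str  # reference-frame
    length: int
    rnap_pair: str | None = None
    rt_pair: str | None = None
    event_qual: int = 0
    context: str = ""


@dataclass(frozen=True)
class GapRecord:
    """One per-base gap observation prior to event collapsing."""

    ref_pos: int
    kind: str  # "deletion" | "insertion"
    base: str
    qual: int


def collapse_indels(raw_gaps: list[GapRecord]) -> list[ErrorEvent]:
    """Merge consecutive per-base gaps into single multi-base events.

    Deletion records at consecutive reference positions merge into one
    deletion; insertion records sharing an anchor merge into one insertion.
    Event quality is the minimum over the contributing records.
    """
    events: list[ErrorEvent] = []
    gaps = sorted(raw_gaps, key=lambda g: (g.ref_pos, g.kind))
    i = 0
    while i < len(gaps):
        g = gaps[i]
        j = i + 1
        bases = [g.base]
        qual = g.qual
        if g.kind == "deletion":
            while (
                j < len(gaps)
                and gaps[j].kind == "deletion"
                and gaps[j].ref_pos == gaps[j - 1].ref_pos + 1
            ):
                bases.append(gaps[j].base)
                qual = min(qual, gaps[j].qual)
                j += 1
            events.append(
                ErrorEvent(
                    "", "", "deletion", g.ref_pos,
                    expected="".join(bases), observed="",
                    length=len(bases), event_qual=qual,
                )
            )
        else:
            while (
                j < len(gaps)
                and gaps[j].kind == "insertion"
                and gaps[j].ref_pos == g.ref_pos
            ):
                bases.append(gaps[j].base)
                qual = min(qual, gaps[j].qual)
                j += 1
            events.append(
                ErrorEvent(
                    "", "", "insertion", g.ref_pos,
                    expected="", observed="".join(bases),
                    length=len(bases), event_qual=qual,
                )
            )
        i = j
    return events


@dataclass
class StrandProfile:
    """An aligned strand expanded to per-reference-position arrays."""

    ref_start: int
    ref_end: int
    base: list[str]  # '-' marks a deleted reference position
    qual: list[int]  # for deletions: min Phred of the flanking read bases
    inserts: dict[int, tuple[str, int]]  # anchor -> (inserted string, min qual)

    def at(self, pos: int) -> tuple[str, int]:
        return self.base[pos - self.ref_start], self.qual[pos - self.ref_start]


def project(aligned: AlignedStrand) -> StrandProfile:
    """Expand an alignment into per-reference-position base/quality arrays."""
    seq, quals = aligned.sequence, aligned.qualities
    base: list[str] = []
    qual: list[int] = []
    inserts: dict[int, tuple[str, int]] = {}
    i = 0
    j = aligned.ref_start
    for op, k in aligned.oplist:
        if op in ("match", "mismatch"):
            base.extend(seq[i : i + k])
            qual.extend(int(q) for q in quals[i : i + k])
            i += k
            j += k
        elif op == "deletion":
            left = int(quals[i - 1]) if i > 0 else 93
            right = int(quals[i]) if i < len(seq) else 93
            flank = min(left, right)
            base.extend("-" * k)
            qual.extend([flank] * k)
            j += k
        else:  # insertion anchored at the next reference base
            q = int(min(quals[i : i + k])) if k else 93
            prev = inserts.get(j)
            if prev:  # terminal overhang adjacent to an internal insertion
                inserts[j] = (prev[0] + seq[i : i + k], min(prev[1], q))
            else:
                inserts[j] = (seq[i : i + k], q)
            i += k
    return StrandProfile(aligned.ref_start, aligned.ref_end, base, qual, inserts)


def _deletion_runs(profile: StrandProfile, lo: int, hi: int) -> dict[int, tuple[int, int]]:
    """Left-aligned deletion runs within [lo, hi): start -> (length, qual)."""
    gaps = [
        GapRecord(pos, "deletion", "", profile.at(pos)[1])
        for pos in range(lo, hi)
        if profile.at(pos)[0] == "-"
    ]
    return {
        e.ref_pos: (e.length, e.event_qual) for e in collapse_indels(gaps)
    }


@dataclass
class DuplexCalls:
    """Attributed events and audit counters for one molecule."""

    first_events: list[ErrorEvent] = field(default_factory=list)
    second_events: list[ErrorEvent] = field(default_factory=list)
    discordant: int = 0
    unconfirmed_first: int = 0
    n_bases: int = 0  # analyzable duplex-covered reference positions


def _context(amplicon: Amplicon, pos: int, window: int) -> str:
    s = amplicon.sequence
    lo, hi = max(0, pos - window), min(len(s), pos + window + 1)
    return s[lo:pos] + "." + s[pos + 1 : hi]


def call_duplex(
    first: AlignedStrand,
    second: AlignedStrand,
    amplicon: Amplicon,
    qual_threshold: int = 93,
    context_window: int = 3,
) -> DuplexCalls:
    """Attribute every duplex discrepancy of one molecule.

    Events below *qual_threshold* (min Phred over event-involved bases, on
    both strands for duplex-confirmed events) are suppressed.  Only the
    analyzable region covered by both strands is considered.
    """
    mid = first.read.molecule_id
    ref = amplicon.sequence
    a0, a1 = amplicon.analyzable
    lo = max(first.ref_start, second.ref_start, a0)
    hi = min(first.ref_end, second.ref_end, a1)
    out = DuplexCalls()
    if hi <= lo:
        return out
    out.n_bases = hi - lo
    p1, p2 = project(first), project(second)

    def ctx(pos: int) -> str:
        return _context(amplicon, pos, context_window)

    # --- substitutions -----------------------------------------------------
    for pos in range(lo, hi):
        b1, q1 = p1.at(pos)
        b2, q2 = p2.at(pos)
        r = ref[pos]
        if b1 == "-" or b2 == "-":
            continue  # handled with the gap runs below
        if b1 == r and b2 == r:
            continue
        if b1 == b2:  # confirmed first-strand substitution
            if min(q1, q2) >= qual_threshold:
                rnap, rt = classify_substitution(r, complement(b1))
                out.first_events.append(
                    ErrorEvent(
                        mid, "first", "substitution", pos, r, b1, 1,
                        rnap_pair=rnap, rt_pair=rt,
                        event_qual=min(q1, q2), context=ctx(pos),
                    )
                )
        elif b1 == r:  # second-strand-only substitution
            if min(q1, q2) >= qual_threshold:
                out.second_events.append(
                    ErrorEvent(
                        mid, "second", "substitution", pos, r, b2, 1,
                        rt_pair=f"d{r}->d{b2}",
                        event_qual=min(q1, q2), context=ctx(pos),
                    )
                )
        elif b2 == r:  # first-strand discrepancy not confirmed
            out.unconfirmed_first += 1
        else:  # both differ, differently: counted in neither class
            out.discordant += 1

    # --- deletions ---------------------------------------------------------
    d1 = _deletion_runs(p1, lo, hi)
    d2 = _deletion_runs(p2, lo, hi)
    for start in sorted(set(d1) | set(d2)):
        k1, q1 = d1.get(start, (0, 93))
        k2, q2 = d2.get(start, (0, 93))
        shared = min(k1, k2)
        if shared and min(q1, q2) >= qual_threshold:
            out.first_events.append(
                ErrorEvent(
                    mid, "first", "deletion", start,
                    expected=ref[start : start + shared], observed="",
                    length=shared, event_qual=min(q1, q2), context=ctx(start),
                )
            )
        elif k1 and not k2:
            out.unconfirmed_first += 1
        if k1 != k2 and shared:
            # shared-length split: the differing tail is a second-strand event
            diff = abs(k1 - k2)
            pos = start + shared
            kind = "deletion" if k2 > k1 else "insertion"
            expected = ref[pos : pos + diff] if kind == "deletion" else ""
            observed = "" if kind == "deletion" else ref[pos : pos + diff]
            if q2 >= qual_threshold:
                out.second_events.append(
                    ErrorEvent(
                        mid, "second", kind, pos, expected, observed,
                        length=diff, event_qual=q2, context=ctx(pos),
                    )
                )
        elif k2 and not k1 and q2 >= qual_threshold:
            out.second_events.append(
                ErrorEvent(
                    mid, "second", "deletion", start,
                    expected=ref[start : start + k2], observed="",
                    length=k2, event_qual=q2, context=ctx(start),
                )
            )

    # --- insertions --------------------------------------------------------
    anchors = {
        p for p in (set(p1.inserts) | set(p2.inserts)) if a0 < p < a1 and lo <= p <= hi
    }
    for pos in sorted(anchors):
        s1, q1 = p1.inserts.get(pos, ("", 93))
        s2, q2 = p2.inserts.get(pos, ("", 93))
        if s1 and s1 == s2:  # confirmed first-strand insertion
            if min(q1, q2) >= qual_threshold:
                out.first_events.append(
                    ErrorEvent(
                        mid, "first", "insertion", pos, "", s1,
                        length=len(s1), event_qual=min(q1, q2), context=ctx(pos),
                    )
                )
        elif s2 and not s1:
            if q2 >= qual_threshold:
                out.second_events.append(
                    ErrorEvent(
                        mid, "second", "insertion", pos, "", s2,
                        length=len(s2), event_qual=q2, context=ctx(pos),
                    )
                )
        elif s1 and not s2:
            out.unconfirmed_first += 1
        elif s1 and s2:
            common = 0
            while common < min(len(s1), len(s2)) and s1[common] == s2[common]:
                common += 1
            if common == 0:
                out.discordant += 1
            else:
                if min(q1, q2) >= qual_threshold:
                    out.first_events.append(
                        ErrorEvent(
                            mid, "first", "insertion", pos, "", s1[:common],
                            length=common, event_qual=min(q1, q2), context=ctx(pos),
                        )
                    )
                longer, q = (s2, q2) if len(s2) > len(s1) else (s1, q1)
                if len(s1) != len(s2) and q >= qual_threshold:
                    kind = "insertion" if len(s2) > len(s1) else "deletion"
                    tail = longer[common:]
                    out.second_events.append(
                        ErrorEvent(
                            mid, "second", kind, pos,
                            expected="" if kind == "insertion" else tail,
                            observed=tail if kind == "insertion" else "",
                            length=len(tail), event_qual=q, context=ctx(pos),
                        )
                    )
    return out


def call_first_strand_errors(
    first: AlignedStrand,
    second: AlignedStrand,
    amplicon: Amplicon,
    qual_threshold: int = 93,
) -> list[ErrorEvent]:
    """Duplex-confirmed first-strand (cDNA vs reference) errors."""
    return call_duplex(first, second, amplicon, qual_threshold).first_events


def call_second_strand_errors(
    first: AlignedStrand,
    second: AlignedStrand,
    amplicon: Amplicon,
    qual_threshold: int = 93,
) -> list[ErrorEvent]:
    """Second-strand-only (reverse transcriptase on DNA template) errors."""
    return call_duplex(first, second, amplicon, qual_threshold).second_events


# ---------------------------------------------------------------------------
# events TSV

_EVENT_COLUMNS = [
    "molecule_id", "strand", "type", "ref_pos", "expected", "observed",
    "length", "rnap_pair", "rt_pair", "event_qual", "context",
]


def events_frame(events: list[ErrorEvent], **labels) -> pd.DataFrame:
    """Tidy events table; extra keyword labels become constant columns."""
    df = pd.DataFrame([vars(e) for e in events], columns=_EVENT_COLUMNS)
    for k, v in labels.items():
        df[k] = v
    return df


def write_events_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"expected": str, "observed": str},
        keep_default_na=False, na_values=[""],
    )
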