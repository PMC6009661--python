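"""Truth-annotated duplex read simulation.

Each simulated molecule passes through three synthesis stages, mirroring the
assay it emulates:

* ``RNAP``  — in-vitro transcription of the reference (RNA-sense) template;
* ``RT1``   — first-strand (cDNA) synthesis from the RNA;
* ``RT2``   — second-strand synthesis from the cDNA.

Errors injected during RNA synthesis propagate into both strands; RT1 errors
appear in the cDNA and are copied faithfully into the second strand; RT2
errors appear in the second strand only.  All sequences are manipulated in
the reference frame internally; the emitted first strand is reverse
complemented into its native orientation.  A base modification is represented
purely as a distinct error model per stage (e.g. an elevated rA->rU rate for
pseudouridine) — the chemistry itself is invisible downstream.

Every injected event is recorded with its stage and a left-aligned reference
coordinate so that downstream calls can be audited against ground truth.
The single dataset seed fans out to per-molecule seeds through
``np.random.default_rng([seed, molecule_index])`` so any molecule is
individually reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .refgen import BASES, BASE_INDEX, Amplicon, complement, revcomp

STAGES = ("RNAP", "RT1", "RT2")

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ErrorModel:
    """Per-stage error probabilities.

    ``sub_rates[t, p]`` is the probability that template/expected base
    ``BASES[t]`` yields product base ``BASES[p]`` (diagonal ignored), in the
    physical frame of the stage (RNA frame for RNAP, cDNA frame for RT1,
    second-strand frame for RT2).  ``context_bias`` optionally multiplies the
    substitution probability depending on the reference base immediately 5'
    of the site, emulating sequence-context-dependent misincorporation.
    Slippage acts per tandem-repeat locus and gains or loses one whole unit.
    """

    sub_rates: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    del_rate: float = 0.0
    ins_rate: float = 0.0
    slippage_rate: float = 0.0
    indel_size_dist: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    context_bias: dict[str, float] | None = None

    def __post_init__(self) -> None:
        m = np.array(self.sub_rates, dtype=float).copy()
        if m.shape != (4, 4):
            raise ValueError("sub_rates must be a 4x4 matrix")
        np.fill_diagonal(m, 0.0)
        if (m < 0).any() or (m > 1).any():
            raise ValueError("substitution probabilities must lie in [0, 1]")
        self.sub_rates = m
        for name in ("del_rate", "ins_rate", "slippage_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        total = float(self.indel_size_dist and sum(self.indel_size_dist.values()))
        if self.indel_size_dist:
            if total <= 0 or any(s < 1 for s in self.indel_size_dist):
                raise ValueError("indel_size_dist must map sizes >= 1 to positive weights")
            self.indel_size_dist = {s: w / total for s, w in self.indel_size_dist.items()}
        bias_max = max(self.context_bias.values(), default=1.0) if self.context_bias else 1.0
        worst = m.sum(axis=1).max() * max(bias_max, 1.0) + self.del_rate + self.ins_rate
        if worst >= 0.5:
            raise ValueError("per-base total event probability must stay below 0.5")

    # -- constructors -------------------------------------------------------

    @classmethod
    def zero(cls) -> "ErrorModel":
        return cls()

    @classmethod
    def uniform(
        cls,
        sub_rate: float = 0.0,
        del_rate: float = 0.0,
        ins_rate: float = 0.0,
        **kwargs,
    ) -> "ErrorModel":
        """Equal substitution probability ``sub_rate/3`` to each wrong base."""
        m = np.full((4, 4), sub_rate / 3.0)
        return cls(sub_rates=m, del_rate=del_rate, ins_rate=ins_rate, **kwargs)

    def with_sub(self, frm: str, to: str, rate: float) -> "ErrorModel":
        """Copy of the model with one substitution cell replaced."""
        m = self.sub_rates.copy()
        m[BASE_INDEX[frm], BASE_INDEX[to]] = rate
        return replace(self, sub_rates=m)

    @property
    def _sizes(self) -> tuple[np.ndarray, np.ndarray]:
        sizes = np.array(sorted(self.indel_size_dist), dtype=int)
        probs = np.array([self.indel_size_dist[s] for s in sizes])
        return sizes, np.cumsum(probs)


@dataclass(frozen=True)
class SimEvent:
    """One injected error, in reference-frame coordinates and bases."""

    stage: str
    type: str  # substitution | deletion | insertion
    ref_pos: int  # left-aligned; for insertions, position of following ref base
    expected: str
    observed: str
    length: int


@dataclass
class SimTruth:
    molecule_id: str
    events: list[SimEvent] = field(default_factory=list)


@dataclass
class SimMolecule:
    molecule_id: str
    first_subreads: list[str]
    second_subreads: list[str]
    truth: SimTruth
    is_chimera: bool = False
    n_passes: int = 1


@dataclass(frozen=True)
class RepeatLocus:
    start: int
    unit: str
    copies: int

    @property
    def end(self) -> int:
        return self.start + len(self.unit) * self.copies


def _primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_tandem_repeats(
    seq: str,
    start: int = 0,
    end: int | None = None,
    max_unit: int = 6,
    min_copies: int = 3,
    min_length: int = 6,
) -> list[RepeatLocus]:
    """Maximal tandem repeats with primitive units, within [start, end)."""
    end = len(seq) if end is None else end
    loci: list[RepeatLocus] = []
    covered: list[tuple[int, int]] = []
    for u in range(1, max_unit + 1):
        i = start
        while i + u <= end:
            unit = seq[i : i + u]
            if not _primitive(unit):
                i += 1
                continue
            c = 1
            while i + (c + 1) * u <= end and seq[i + c * u : i + (c + 1) * u] == unit:
                c += 1
            if c >= min_copies and c * u >= min_length:
                span = (i, i + c * u)
                if not any(s < span[1] and span[0] < e for s, e in covered):
                    loci.append(RepeatLocus(i, unit, c))
                    covered.append(span)
                i += c * u
            else:
                i += 1
    return sorted(loci, key=lambda l: l.start)


# ---------------------------------------------------------------------------
# mutation engine (reference-frame token lists)

# token = (ref_pos, base, is_insert); inserted tokens carry the anchor position
# of the following reference base.


def _left_align_del(ref: str, floor: int, start: int, bases: str) -> tuple[int, str]:
    k = len(bases)
    while start - 1 >= floor and ref[start - 1] == ref[start + k - 1]:
        start -= 1
        bases = ref[start : start + k]
    return start, bases


def _left_align_ins(ref: str, floor: int, anchor: int, s: str) -> tuple[int, str]:
    while anchor - 1 >= floor and s[-1] == ref[anchor - 1]:
        s = ref[anchor - 1] + s[:-1]
        anchor -= 1
    return anchor, s


def _apply_slippage(
    tokens: list[tuple[int, str, bool]],
    loci: list[RepeatLocus],
    rate: float,
    rng: np.random.Generator,
    stage: str,
    events: list[SimEvent],
) -> list[tuple[int, str, bool]]:
    if rate <= 0 or not loci:
        return tokens
    for locus in loci:
        if rng.random() >= rate:
            continue
        u = len(locus.unit)
        idx = [
            k
            for k, (pos, _, ins) in enumerate(tokens)
            if not ins and locus.start <= pos < locus.end
        ]
        if len(idx) != locus.end - locus.start:
            continue  # locus already disturbed by an earlier stage
        first = idx[0]
        if rng.random() < 0.5:  # gain one unit (left-aligned at locus start)
            ins_tokens = [(locus.start, b, True) for b in locus.unit]
            tokens = tokens[:first] + ins_tokens + tokens[first:]
            events.append(
                SimEvent(stage, "insertion", locus.start, "", locus.unit, u)
            )
        else:  # lose one unit
            tokens = tokens[:first] + tokens[first + u :]
            events.append(
                SimEvent(stage, "deletion", locus.start, locus.unit, "", u)
            )
    return tokens


def _apply_stage(
    tokens: list[tuple[int, str, bool]],
    model: ErrorModel,
    frame: str,
    amplicon: Amplicon,
    rng: np.random.Generator,
    stage: str,
    events: list[SimEvent],
    loci: list[RepeatLocus] | None = None,
) -> list[tuple[int, str, bool]]:
    """Apply one synthesis stage to a reference-frame token list.

    ``frame`` selects how the model's (template -> product) matrix maps onto
    reference-frame bases: for ``cdna`` the expected base is the complement of
    the current reference-frame base and the product is complemented back.
    """
    tokens = _apply_slippage(tokens, loci or [], model.slippage_rate, rng, stage, events)
    row_tot = model.sub_rates.sum(axis=1)
    if row_tot.max() == 0 and model.del_rate == 0 and model.ins_rate == 0:
        return tokens

    ref = amplicon.sequence
    a0, a1 = amplicon.analyzable
    sizes, size_cum = model._sizes
    cum = np.cumsum(model.sub_rates, axis=1)
    bias_map = model.context_bias or {}
    p_del, p_ins = model.del_rate, model.ins_rate

    out: list[tuple[int, str, bool]] = []
    n = len(tokens)
    u = rng.random(n)
    i = 0
    while i < n:
        pos, base, is_ins = tokens[i]
        if not (a0 <= pos < a1):
            out.append(tokens[i])
            i += 1
            continue
        row = BASE_INDEX[_COMP1[base]] if frame == "cdna" else BASE_INDEX[base]
        bias = bias_map.get(ref[pos - 1], 1.0) if bias_map and pos > 0 else 1.0
        p_sub = row_tot[row] * bias
        r = u[i]
        if r < p_sub:
            c = int(np.searchsorted(cum[row] * bias, r, side="right"))
            prod = BASES[c]
            new = _COMP1[prod] if frame == "cdna" else prod
            events.append(SimEvent(stage, "substitution", pos, base, new, 1))
            out.append((pos, new, is_ins))
            i += 1
        elif r < p_sub + p_del:
            size = int(sizes[np.searchsorted(size_cum, rng.random(), side="right")])
            k = i
            deleted: list[tuple[int, str, bool]] = []
            while k < n and len(deleted) < size and a0 <= tokens[k][0] < a1:
                deleted.append(tokens[k])
                k += 1
            bases_del = "".join(t[1] for t in deleted)
            start = deleted[0][0]
            if all(not t[2] for t in deleted) and [t[0] for t in deleted] == list(
                range(start, start + len(deleted))
            ):
                start, bases_del = _left_align_del(ref, a0, start, bases_del)
            events.append(
                SimEvent(stage, "deletion", start, bases_del, "", len(deleted))
            )
            i = k
        elif r < p_sub + p_del + p_ins:
            out.append(tokens[i])
            # anchor at the next reference base; keep anchors interior so
            # truth events stay inside the analyzable region
            anchor = None
            for k in range(i + 1, n):
                if not tokens[k][2]:
                    anchor = tokens[k][0]
                    break
            if anchor is not None and a0 < anchor < a1:
                size = int(sizes[np.searchsorted(size_cum, rng.random(), side="right")])
                ins_bases = "".join(
                    BASES[int(b)] for b in rng.integers(0, 4, size=size)
                )
                anchor_la, ins_la = _left_align_ins(ref, a0, anchor, ins_bases)
                events.append(
                    SimEvent(stage, "insertion", anchor_la, "", ins_la, size)
                )
                out.extend((anchor, b, True) for b in ins_bases)
            i += 1
        else:
            out.append(tokens[i])
            i += 1
    return out


@dataclass
class SimulatedStrands:
    first_strand: str  # native orientation (reverse complement frame)
    second_strand: str  # reference-sense
    truth: SimTruth


def simulate_molecule(
    amplicon: Amplicon,
    rnap: ErrorModel,
    rt1: ErrorModel,
    rt2: ErrorModel,
    seed: int | np.random.Generator | None = None,
    molecule_id: str = "mol",
    loci: list[RepeatLocus] | None = None,
) -> SimulatedStrands:
    """Simulate one molecule through RNAP -> RT1 -> RT2.

    Returns the first strand in its native (reverse-complement) orientation,
    the second strand in reference sense, and the per-stage truth log.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if loci is None:
        a0, a1 = amplicon.analyzable
        loci = find_tandem_repeats(amplicon.sequence, a0, a1)
    events: list[SimEvent] = []
    tokens = [(i, b, False) for i, b in enumerate(amplicon.sequence)]
    rna = _apply_stage(tokens, rnap, "rna", amplicon, rng, "RNAP", events, loci)
    first = _apply_stage(rna, rt1, "cdna", amplicon, rng, "RT1", events, loci)
    second = _apply_stage(list(first), rt2, "second", amplicon, rng, "RT2", events, loci)
    first_seq = "".join(t[1] for t in first)
    second_seq = "".join(t[1] for t in second)
    return SimulatedStrands(
        first_strand=revcomp(first_seq),
        second_strand=second_seq,
        truth=SimTruth(molecule_id, events),
    )


def simulate_subreads(
    strand_seq: str,
    n_passes: int,
    raw_error: float,
    seed: int | np.random.Generator | None = None,
    sub_frac: float = 0.9,
    del_frac: float = 0.05,
) -> list[str]:
    """Independently noised copies of *strand_seq* (one per pass).

    Raw noise is ``raw_error`` per base, split ``sub_frac`` substitutions,
    ``del_frac`` single-base deletions and the rest single-base insertions —
    a crude stand-in for raw single-pass sequencing error.
    """
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    if not 0.0 <= raw_error <= 0.3:
        raise ValueError("raw_error must lie in [0, 0.3]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if raw_error == 0.0:
        return [strand_seq] * n_passes
    L = len(strand_seq)
    reads: list[str] = []
    for _ in range(n_passes):
        hits = np.nonzero(rng.random(L) < raw_error)[0]
        if hits.size == 0:
            reads.append(strand_seq)
            continue
        parts: list[str] = []
        prev = 0
        for pos in hits:
            parts.append(strand_seq[prev:pos])
            t = rng.random()
            b = strand_seq[pos]
            if t < sub_frac:
                parts.append(BASES[(BASE_INDEX[b] + 1 + int(rng.integers(3))) % 4])
            elif t < sub_frac + del_frac:
                pass  # deleted
            else:
                parts.append(BASES[int(rng.integers(4))] + b)
            prev = pos + 1
        parts.append(strand_seq[prev:])
        reads.append("".join(parts))
    return reads


def make_chimera(
    mol_a: str, mol_b: str, breakpoint: int, breakpoint_b: int | None = None
) -> str:
    """Fuse the prefix of *mol_a* with the suffix of *mol_b*.

    A second breakpoint models loop-out template switching, which changes the
    product length (the signature the read-length filter catches).
    """
    bp_b = breakpoint if breakpoint_b is None else breakpoint_b
    if not (0 <= breakpoint <= len(mol_a)) or not (0 <= bp_b <= len(mol_b)):
        raise ValueError("breakpoints must lie within both molecules")
    return mol_a[:breakpoint] + mol_b[bp_b:]


def simulate_dataset(
    amplicon: Amplicon,
    rnap: ErrorModel,
    rt1: ErrorModel,
    rt2: ErrorModel,
    n_molecules: int,
    seed: int,
    n_passes: int = 15,
    raw_error: float = 0.0,
    chimera_rate: float = 0.0,
) -> list[SimMolecule]:
    """Simulate a full truth-annotated dataset of duplex molecules.

    Chimeric molecules (template-switching artifacts) fuse two independently
    simulated molecules at offset breakpoints; their truth events are cleared
    and they are flagged so filter audits can count them.
    """
    a0, a1 = amplicon.analyzable
    loci = find_tandem_repeats(amplicon.sequence, a0, a1)
    L = len(amplicon.sequence)
    molecules: list[SimMolecule] = []
    for i in range(n_molecules):
        rng = np.random.default_rng([seed, i])
        mid = f"mol{i:06d}"
        sim = simulate_molecule(amplicon, rnap, rt1, rt2, rng, mid, loci)
        first_native, second = sim.first_strand, sim.second_strand
        is_chimera = chimera_rate > 0 and rng.random() < chimera_rate
        if is_chimera:
            partner = simulate_molecule(
                amplicon, rnap, rt1, rt2, np.random.default_rng([seed, i, 1]), mid, loci
            )
            bp_a, bp_b = L // 3, (2 * L) // 3
            first_ref_frame = make_chimera(
                revcomp(first_native), revcomp(partner.first_strand), bp_a, bp_b
            )
            first_native = revcomp(first_ref_frame)
            second = make_chimera(second, partner.second_strand, bp_a, bp_b)
            sim = SimulatedStrands(first_native, second, SimTruth(mid, []))
        molecules.append(
            SimMolecule(
                molecule_id=mid,
                first_subreads=simulate_subreads(first_native, n_passes, raw_error, rng),
                second_subreads=simulate_subreads(second, n_passes, raw_error, rng),
                truth=sim.truth,
                is_chimera=is_chimera,
                n_passes=n_passes,
            )
        )
    return molecules


def truth_frame(molecules: list[SimMolecule]) -> pd.DataFrame:
    """Flatten per-molecule truth logs into a tidy table."""
    rows = [
        {
            "molecule_id": m.molecule_id,
            "stage": e.stage,
            "type": e.type,
            "ref_pos": e.ref_pos,
            "expected": e.expected,
            "observed": e.observed,
            "length": e.length,
            "is_chimera": m.is_chimera,
        }
        for m in molecules
        for e in m.truth.events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "molecule_id", "stage", "type", "ref_pos",
            "expected", "observed", "length", "is_chimera",
        ],
    )


# ---------------------------------------------------------------------------
# FASTQ / TSV plumbing


def write_subreads_fastq(molecules: list[SimMolecule], path: str | Path) -> None:
    """Strand-tagged subread FASTQ; read names encode molecule|strand|pass."""
    with open(path, "w") as fh:
        for m in molecules:
            for strand, reads in (("first", m.first_subreads), ("second", m.second_subreads)):
                for j, seq in enumerate(reads):
                    fh.write(f"@{m.molecule_id}|{strand}|{j}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_subreads_fastq(path: str | Path) -> dict[tuple[str, str], list[str]]:
    """Group subreads back by (molecule_id, strand)."""
    from Bio import SeqIO

    groups: dict[tuple[str, str], list[str]] = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        name, strand, _ = rec.id.split("|")
        groups.setdefault((name, strand), []).append(str(rec.seq))
    return groups


def write_truth_tsv(molecules: list[SimMolecule], path: str | Path) -> None:
    truth_frame(molecules).to_csv(path, sep="\t", index=False)
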