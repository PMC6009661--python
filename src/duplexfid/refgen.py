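"""Reference amplicon modelling and synthetic template generation.

Templates emulate the artificial amplicons used in duplex fidelity assays:
near-equimolar base composition with every overlapping 4-mer represented in the
analyzable region, no long homopolymer runs, and primer regions at both ends
that are excluded from error-rate denominators.  The all-4-mer property is
obtained from a randomized Eulerian circuit over the order-4 de Bruijn graph;
a circuit over all 256 4-mers automatically caps homopolymer runs at 4 (a run
of 5 would require traversing a homopolymer edge twice).
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")

#: modification label -> the canonical DNA-alphabet base it replaces in the RNA
MODIFICATION_TARGETS = {
    "none": None,
    "m6A": "A",
    "pseudouridine": "T",
    "m5C": "C",
    "m5U": "T",
    "hm5U": "T",
}


class InfeasibleConstraintError(ValueError):
    """Sequence constraints cannot be jointly satisfied."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP_TABLE)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP_TABLE)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest homopolymer run in *seq*."""
    return max(len(list(g)) for _, g in itertools.groupby(seq)) if seq else 0


def kmer_census(seq: str, k: int = 4) -> set[str]:
    """All overlapping k-mers present in *seq*."""
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


@dataclass(frozen=True)
class Amplicon:
    """A reference amplicon on the RNA-sense strand, DNA alphabet.

    ``primer5``/``primer3`` are half-open 0-based intervals at the 5' and 3'
    ends; the analyzable region is everything between them.  ``modification``
    names which canonical base is fully substituted in the RNA (chemistry is
    invisible to the pipeline; the label is carried for grouping).
    """

    id: str
    sequence: str
    primer5: tuple[int, int]
    primer3: tuple[int, int]
    modification: str = "none"

    def __post_init__(self) -> None:
        seq = self.sequence
        if len(seq) < 100:
            raise ValueError(f"amplicon length {len(seq)} < 100")
        if set(seq) - set(BASES):
            raise ValueError("sequence contains non-ACGT characters")
        p5, p3 = self.primer5, self.primer3
        for name, (s, e) in (("primer5", p5), ("primer3", p3)):
            if not (0 <= s < e <= len(seq)):
                raise ValueError(f"{name} interval {s, e} outside [0, {len(seq)})")
        if p5[1] > p3[0]:
            raise ValueError("primer intervals overlap")
        if self.modification not in MODIFICATION_TARGETS:
            raise ValueError(f"unknown modification label {self.modification!r}")
        if self.analyzable_length <= 0:
            raise ValueError("analyzable region is empty")

    @property
    def analyzable(self) -> tuple[int, int]:
        """Half-open interval of the analyzable (primer-free) region."""
        return (self.primer5[1], self.primer3[0])

    @property
    def analyzable_length(self) -> int:
        a0, a1 = self.primer5[1], self.primer3[0]
        return a1 - a0

    @property
    def analyzable_sequence(self) -> str:
        a0, a1 = self.analyzable
        return self.sequence[a0:a1]

    def is_analyzable(self, pos: int) -> bool:
        a0, a1 = self.analyzable
        return a0 <= pos < a1


def _random_bases(rng: np.random.Generator, n: int, max_run: int, tail: str = "") -> str:
    """Random bases appended after *tail* without creating runs > max_run."""
    out: list[str] = []
    run_char = tail[-1] if tail else ""
    run_len = 0
    for c in reversed(tail):
        if c != run_char:
            break
        run_len += 1
    for _ in range(n):
        if run_len >= max_run:
            choices = [b for b in BASES if b != run_char]
        else:
            choices = list(BASES)
        c = choices[int(rng.integers(len(choices)))]
        if c == run_char:
            run_len += 1
        else:
            run_char, run_len = c, 1
        out.append(c)
    return "".join(out)


def _debruijn_supersequence(rng: np.random.Generator, kmers: list[str]) -> str:
    """Randomized Eulerian circuit reading off every k-mer in *kmers* once."""
    adj: dict[str, list[str]] = {}
    indeg: dict[str, int] = {}
    for km in kmers:
        adj.setdefault(km[:-1], []).append(km[-1])
        indeg[km[1:]] = indeg.get(km[1:], 0) + 1
    for node, nxt in adj.items():
        if len(nxt) != indeg.get(node, 0):
            raise InfeasibleConstraintError(
                "k-mer set does not admit an Eulerian circuit"
            )
        order = rng.permutation(len(nxt))
        adj[node] = [nxt[i] for i in order]
    start = sorted(adj)[int(rng.integers(len(adj)))]
    stack = [start]
    path: list[str] = []
    while stack:
        node = stack[-1]
        if adj.get(node):
            c = adj[node].pop()
            stack.append(node[1:] + c)
        else:
            path.append(stack.pop())
    if len(path) != len(kmers) + 1:
        raise InfeasibleConstraintError("k-mer graph is not connected")
    path.reverse()
    return path[0] + "".join(node[-1] for node in path[1:])


def generate_reference(
    length: int = 500,
    *,
    max_homopolymer: int = 4,
    require_all_4mers: bool = True,
    seed: int | None = None,
    primer_len: int = 20,
    modification: str = "none",
    label: str | None = None,
    relax_infeasible_kmers: bool = False,
    max_retries: int = 50,
) -> Amplicon:
    """Generate a synthetic reference amplicon.

    When ``require_all_4mers`` is set the analyzable region contains every
    4-mer compatible with the homopolymer cap.  With ``max_homopolymer < 4``
    the homopolymer 4-mers (AAAA, ...) are impossible; this raises
    :class:`InfeasibleConstraintError` unless ``relax_infeasible_kmers`` is
    set, in which case the target set is every 4-mer without a run longer
    than the cap.

    The result is reproducible from *seed*.
    """
    if length < 100:
        raise ValueError("length must be >= 100")
    if max_homopolymer < 1:
        raise ValueError("max_homopolymer must be >= 1")
    rng = np.random.default_rng(seed)
    analyzable_len = length - 2 * primer_len

    target_kmers: list[str] = []
    if require_all_4mers:
        if max_homopolymer < 4 and not relax_infeasible_kmers:
            raise InfeasibleConstraintError(
                "all 256 4-mers include homopolymer runs of 4; "
                "raise max_homopolymer to >= 4 or set relax_infeasible_kmers"
            )
        target_kmers = [
            "".join(p)
            for p in itertools.product(BASES, repeat=4)
            if max_homopolymer_run("".join(p)) <= max_homopolymer
        ]
        if analyzable_len < len(target_kmers) + 3:
            raise ValueError(
                f"analyzable region ({analyzable_len} bases) too short for "
                f"{len(target_kmers)} overlapping 4-mers"
            )

    for _ in range(max_retries):
        core = _debruijn_supersequence(rng, target_kmers) if require_all_4mers else ""
        p5 = _random_bases(rng, primer_len, max_homopolymer)
        if core and max_homopolymer_run(p5[-max_homopolymer:] + core[: max_homopolymer + 1]) > max_homopolymer:
            continue  # bad junction; retry with fresh randomness
        body = p5 + core
        pad = _random_bases(rng, analyzable_len - len(core), max_homopolymer, tail=body)
        body += pad
        p3 = _random_bases(rng, primer_len, max_homopolymer, tail=body)
        seq = body + p3
        if max_homopolymer_run(seq) > max_homopolymer:
            continue
        amp = Amplicon(
            id=label or f"synth-{length}",
            sequence=seq,
            primer5=(0, primer_len),
            primer3=(length - primer_len, length),
            modification=modification,
        )
        if require_all_4mers:
            seen = kmer_census(amp.analyzable_sequence, 4)
            if not set(target_kmers) <= seen:
                continue
        return amp
    raise InfeasibleConstraintError(
        f"could not satisfy constraints within {max_retries} attempts"
    )


def insert_repeat(amplicon: Amplicon, unit: str, copies: int, position: int) -> Amplicon:
    """Insert ``copies`` tandem copies of ``unit`` at ``position``.

    Used to provoke replication slippage at repeat elements in simulations.
    The 3' primer interval shifts right by the inserted length.
    """
    if not 1 <= len(unit) <= 6:
        raise ValueError("repeat unit length must be in [1, 6]")
    if set(unit) - set(BASES):
        raise ValueError("repeat unit contains non-ACGT characters")
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if copies == 0:
        return amplicon
    if not amplicon.is_analyzable(position):
        raise ValueError(f"insertion position {position} outside the analyzable region")
    ins = unit * copies
    seq = amplicon.sequence[:position] + ins + amplicon.sequence[position:]
    p3 = (amplicon.primer3[0] + len(ins), amplicon.primer3[1] + len(ins))
    return replace(amplicon, sequence=seq, primer3=p3)


# ---------------------------------------------------------------------------
# FASTA + JSON-sidecar I/O


def write_reference(amplicon: Amplicon, fasta_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    fasta_path = Path(fasta_path)
    rec = SeqRecord(
        Seq(amplicon.sequence),
        id=amplicon.id,
        description=f"modification={amplicon.modification}",
    )
    SeqIO.write([rec], str(fasta_path), "fasta")
    sidecar = Path(sidecar_path) if sidecar_path else fasta_path.with_suffix(fasta_path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "id": amplicon.id,
                "primer5": list(amplicon.primer5),
                "primer3": list(amplicon.primer3),
                "modification": amplicon.modification,
            },
            indent=2,
        )
    )


def read_reference(
    fasta_path: str | Path,
    sidecar_path: str | Path | None = None,
    primer_len: int = 20,
) -> Amplicon:
    """Read an amplicon FASTA; primer intervals come from the JSON sidecar
    when present, else default to *primer_len* bases at each end."""
    fasta_path = Path(fasta_path)
    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    seq = str(rec.seq).upper()
    sidecar = Path(sidecar_path) if sidecar_path else fasta_path.with_suffix(fasta_path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return Amplicon(
            id=meta.get("id", rec.id),
            sequence=seq,
            primer5=tuple(meta["primer5"]),
            primer3=tuple(meta["primer3"]),
            modification=meta.get("modification", "none"),
        )
    return Amplicon(
        id=rec.id,
        sequence=seq,
        primer5=(0, primer_len),
        primer3=(len(seq) - primer_len, len(seq)),
    )
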