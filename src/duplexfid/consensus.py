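"""Per-strand consensus from subreads, with consensus-level filtering.

The consensus here is a deliberately simple column-wise majority vote: every
subread is aligned pairwise (unit-cost edit distance, via edlib) to a draft —
the longest subread, ties broken lexicographically so the result does not
depend on input order — and votes are tallied per draft column.  Per-base
quality is the Phred-scaled column agreement, capped at 93, the saturation
value of the consensus quality scale this pipeline's event filter assumes.
Externally produced consensus FASTQ can be dropped in instead.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .refgen import BASE_INDEX, BASES

MAX_QUAL = 93
#: floor on the disagreement fraction, so perfect columns hit exactly Q93
_MIN_DISAGREE = 10.0 ** -9.3

_SYMBOLS = BASES + "-"
_GAP = 4


def phred_from_agreement(f: float) -> int:
    """Phred-scaled column agreement, monotone in f and capped at 93."""
    return int(min(MAX_QUAL, round(-10.0 * math.log10(max(1.0 - f, _MIN_DISAGREE)))))


@dataclass
class StrandRead:
    """A per-molecule, per-strand consensus read in native orientation."""

    molecule_id: str
    strand: str  # "first" | "second"
    sequence: str
    qualities: np.ndarray
    n_passes: int

    def __post_init__(self) -> None:
        if self.strand not in ("first", "second"):
            raise ValueError(f"strand must be 'first' or 'second', got {self.strand!r}")
        q = np.asarray(self.qualities, dtype=np.int16)
        if q.shape != (len(self.sequence),):
            raise ValueError("qualities length must equal sequence length")
        if q.size and (q.min() < 0 or q.max() > MAX_QUAL):
            raise ValueError(f"qualities must lie in [0, {MAX_QUAL}]")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")
        self.qualities = q


@dataclass(frozen=True)
class FilterDecision:
    accepted: bool
    reason: str | None = None


def _parse_cigar(cigar: str):
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            yield num, ch
            num = 0


def build_consensus(
    subreads: list[str], molecule_id: str = "", strand: str = "first"
) -> StrandRead:
    """Column-wise majority-vote consensus over *subreads*.

    The draft is the longest subread (ties broken lexicographically) and is
    polished by repeated re-voting: errors private to the draft, in
    particular deleted bases whose recovery votes would otherwise split
    across alignment anchors, are corrected in the first round and the vote
    is repeated against the cleaner draft until it reaches a fixed point.
    Column ties are broken by fixed base priority (A < C < G < T, gap last),
    so permuting the subreads yields an identical consensus.
    """
    if not subreads:
        raise ValueError("at least one subread is required")
    n = len(subreads)
    if len(set(subreads)) == 1:
        seq = subreads[0]
        return StrandRead(molecule_id, strand, seq, np.full(len(seq), MAX_QUAL), n)

    max_len = max(len(s) for s in subreads)
    draft = min(s for s in subreads if len(s) == max_len)
    for _ in range(8):
        seq, qual, stats = _vote(subreads, draft)
        if seq != draft:
            draft = seq
            continue
        # at the voting fixed point, repair residual ambiguities (mostly
        # homopolymer-adjacent, where per-read optimal alignments scatter
        # votes) by maximum parsimony over the subreads
        repaired = _parsimony_repair(subreads, seq, stats)
        if repaired is None:
            break
        draft = repaired
    return StrandRead(molecule_id, strand, seq, qual, n)


def _total_distance(subreads: list[str], seq: str) -> int:
    return sum(edlib.align(s, seq, mode="NW")["editDistance"] for s in subreads)


def _parsimony_repair(
    subreads: list[str], seq: str, stats: tuple
) -> str | None:
    """Try vote-suggested single edits; keep the one that most reduces the
    total edit distance of the subreads to the consensus, if any does."""
    votes, ins_votes = stats
    n = len(subreads)
    candidates: list[str] = []
    counts = votes[np.arange(len(seq)), np.argmax(votes * 8 - np.arange(5), axis=1)]
    for j in np.nonzero(counts < 0.8 * n)[0]:
        j = int(j)
        for b in range(4):
            if _SYMBOLS[b] != seq[j] and votes[j, b] >= 2:
                candidates.append(seq[:j] + _SYMBOLS[b] + seq[j + 1 :])
        if votes[j, _GAP] >= 2:
            candidates.append(seq[:j] + seq[j + 1 :])
    for anchor in sorted(ins_votes):
        bucket = ins_votes[anchor]
        if sum(bucket.values()) >= 2:
            best = min(bucket, key=lambda s_: (-bucket[s_], s_))
            candidates.append(seq[:anchor] + best + seq[anchor:])
    if not candidates:
        return None
    base = _total_distance(subreads, seq)
    scored = [(dist, cand) for cand in candidates if (dist := _total_distance(subreads, cand)) < base]
    if not scored:
        return None
    return min(scored)[1]


def _vote(subreads: list[str], draft: str) -> tuple[str, np.ndarray, tuple]:
    """One round of column-wise majority voting against *draft*."""
    n = len(subreads)
    D = len(draft)
    votes = np.zeros((D, 5), dtype=np.int32)
    ins_votes: dict[int, dict[str, int]] = {}

    draft_idx = np.fromiter((BASE_INDEX[c] for c in draft), dtype=np.int64, count=D)
    for s in subreads:
        if s == draft:
            votes[np.arange(D), draft_idx] += 1
            continue
        aln = edlib.align(s, draft, task="path", mode="NW")
        pos_chunks: list[np.ndarray] = []
        sym_chunks: list[np.ndarray] = []
        dpos = spos = 0
        for k, op in _parse_cigar(aln["cigar"]):
            if op in "=XM":
                pos_chunks.append(np.arange(dpos, dpos + k))
                sym_chunks.append(
                    np.fromiter((BASE_INDEX[c] for c in s[spos : spos + k]), dtype=np.int64, count=k)
                )
                dpos += k
                spos += k
            elif op == "D":  # absent from subread: gap votes against draft columns
                pos_chunks.append(np.arange(dpos, dpos + k))
                sym_chunks.append(np.full(k, _GAP, dtype=np.int64))
                dpos += k
            elif op == "I":  # extra subread bases anchored before draft column dpos
                ins = s[spos : spos + k]
                bucket = ins_votes.setdefault(dpos, {})
                bucket[ins] = bucket.get(ins, 0) + 1
                spos += k
        np.add.at(votes, (np.concatenate(pos_chunks), np.concatenate(sym_chunks)), 1)

    # winner per column: highest count, ties by symbol priority (gap last)
    winner = np.argmax(votes * 8 - np.arange(5), axis=1)
    counts = votes[np.arange(D), winner]
    frac = counts / n
    quals = np.minimum(
        MAX_QUAL,
        np.rint(-10.0 * np.log10(np.maximum(1.0 - frac, _MIN_DISAGREE))),
    ).astype(np.int16)

    seq_parts: list[str] = []
    qual_parts: list[np.ndarray] = []

    def emit_insertion(anchor: int) -> None:
        # Optimal per-read alignments can represent the same missing-draft
        # base in structurally different ways (notably around homopolymer
        # runs), scattering its support; a plurality vote over one third of
        # the reads recovers it while random per-read noise (~raw_error/20
        # per base per anchor) stays far below the threshold.
        bucket = ins_votes.get(anchor)
        if not bucket:
            return
        support = sum(bucket.values())
        if 3 * support <= n:
            return
        best = min(bucket, key=lambda s_: (-bucket[s_], s_))
        q = phred_from_agreement(support / n)
        seq_parts.append(best)
        qual_parts.append(np.full(len(best), q, dtype=np.int16))

    for j in range(D):
        emit_insertion(j)
        if winner[j] != _GAP:
            seq_parts.append(_SYMBOLS[winner[j]])
            qual_parts.append(quals[j : j + 1])
    emit_insertion(D)

    seq = "".join(seq_parts)
    qual = np.concatenate(qual_parts) if qual_parts else np.zeros(0, dtype=np.int16)
    return seq, qual, (votes, ins_votes)


def filter_consensus(read: StrandRead, min_passes: int = 15) -> FilterDecision:
    """Reject consensus reads built from fewer than *min_passes* passes."""
    if read.n_passes < min_passes:
        return FilterDecision(False, "min_passes")
    return FilterDecision(True)


# ---------------------------------------------------------------------------
# consensus FASTQ I/O (pass count carried in the header tag)


def write_consensus_fastq(reads: list[StrandRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.molecule_id}|{r.strand} np={r.n_passes}\n{r.sequence}\n+\n{qual}\n")


def read_consensus_fastq(path: str | Path) -> list[StrandRead]:
    reads: list[StrandRead] = []
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            name, _, rest = header[1:].partition(" ")
            mid, _, strand = name.partition("|")
            n_passes = 1
            for tok in rest.split():
                if tok.startswith("np="):
                    n_passes = int(tok[3:])
            reads.append(
                StrandRead(
                    mid,
                    strand or "first",
                    seq,
                    np.array([ord(c) - 33 for c in qual], dtype=np.int16),
                    n_passes,
                )
            )
    return reads
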