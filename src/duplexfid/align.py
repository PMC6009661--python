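"""Semi-global affine-gap alignment to the reference and read-level filters.

The internal aligner is a Gotoh dynamic program with free terminal gaps
(overlap alignment): leading/trailing unaligned reference bases become
``ref_start``/``ref_end`` offsets and unaligned read overhang is recorded as
terminal insertions, so reads that do not span the reference fail the span
filters rather than being force-fit.  Indels are left-aligned against the
reference after traceback so that first- and second-strand events at the same
locus coincide positionally — a precondition for duplex attribution.
Alternatively, externally produced SAM alignments can be read in.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .consensus import FilterDecision, StrandRead
from .refgen import Amplicon, revcomp

_NEG = -(10**9)

#: map ASCII byte -> base index (A0 C1 G2 T3)
_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


class AlignmentError(ValueError):
    """Read could not be aligned above the score floor."""


@dataclass(frozen=True)
class Scoring:
    """BWA-MEM-like affine scores; a gap of length k costs open + k*extend."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    min_score_per_base: float = 0.0

    #: mapping quality assigned to unique internal alignments
    MAPQ_SENTINEL = 60


@dataclass
class AlignedStrand:
    """A strand read projected into reference coordinates.

    ``sequence``/``qualities`` are in reference frame (first-strand reads are
    reverse-complemented before alignment and flagged via ``orientation``).
    ``oplist`` is run-length encoded in reference order over ops
    match/mismatch/insertion/deletion.
    """

    read: StrandRead
    sequence: str
    qualities: np.ndarray
    oplist: list[tuple[str, int]]
    ref_start: int
    ref_end: int
    mapping_quality: int
    orientation: str  # "as-is" | "reverse-complemented"
    supplementary_count: int = 0
    score: int = 0

    def __post_init__(self) -> None:
        ref_len = sum(k for op, k in self.oplist if op in ("match", "mismatch", "deletion"))
        read_len = sum(k for op, k in self.oplist if op in ("match", "mismatch", "insertion"))
        if ref_len != self.ref_end - self.ref_start:
            raise ValueError("reference-consuming op lengths do not match ref span")
        if read_len != len(self.sequence):
            raise ValueError("read-consuming op lengths do not match read length")


@njit(cache=True)
def _gotoh_kernel(x, y, ma, mi, go, ge):  # pragma: no cover - exercised via wrapper
    m = x.shape[0]
    n = y.shape[0]
    H = np.zeros((m + 1, n + 1), np.int64)
    E = np.full((m + 1, n + 1), _NEG, np.int64)
    F = np.full((m + 1, n + 1), _NEG, np.int64)
    pH = np.zeros((m + 1, n + 1), np.uint8)  # 0 diag, 1 from E, 2 from F
    pE = np.zeros((m + 1, n + 1), np.uint8)  # 1 open, 0 extend
    pF = np.zeros((m + 1, n + 1), np.uint8)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            eo = H[i, j - 1] + go + ge
            ee = E[i, j - 1] + ge
            if eo >= ee:
                E[i, j] = eo
                pE[i, j] = 1
            else:
                E[i, j] = ee
            fo = H[i - 1, j] + go + ge
            fe = F[i - 1, j] + ge
            if fo >= fe:
                F[i, j] = fo
                pF[i, j] = 1
            else:
                F[i, j] = fe
            s = ma if x[i - 1] == y[j - 1] else mi
            best = H[i - 1, j - 1] + s
            p = 0
            if E[i, j] > best:
                best = E[i, j]
                p = 1
            if F[i, j] > best:
                best = F[i, j]
                p = 2
            H[i, j] = best
            pH[i, j] = p
    # free terminal gaps: best score over last row / last column
    bi, bj, bs = m, n, H[m, n]
    for j in range(n + 1):
        if H[m, j] > bs:
            bs = H[m, j]
            bi, bj = m, j
    for i in range(m + 1):
        if H[i, n] > bs:
            bs = H[i, n]
            bi, bj = i, n
    ops = np.empty(m + n, np.uint8)  # 0 match, 1 mismatch, 2 ins, 3 del
    k = 0
    i, j = bi, bj
    st = 0
    while not (st == 0 and (i == 0 or j == 0)):
        if st == 0:
            p = pH[i, j]
            if p == 0:
                ops[k] = 0 if x[i - 1] == y[j - 1] else 1
                k += 1
                i -= 1
                j -= 1
            elif p == 1:
                st = 1
            else:
                st = 2
        elif st == 1:
            ops[k] = 3
            k += 1
            opened = pE[i, j] == 1
            j -= 1
            if opened:
                st = 0
        else:
            ops[k] = 2
            k += 1
            opened = pF[i, j] == 1
            i -= 1
            if opened:
                st = 0
    return bs, ops[:k], i, j, bi, bj


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_OP_CHARS = "MXID"


def align_semiglobal(
    read_seq: str, ref_seq: str, scoring: Scoring = Scoring()
) -> tuple[int, list[str], int, int]:
    """Overlap-align *read_seq* to *ref_seq*.

    Returns (score, per-base op characters M/X/I/D in reference order,
    ref_start, ref_end).  Terminal read overhang appears as I ops.
    """
    if not read_seq:
        raise AlignmentError("empty read")
    score, ops, i0, j0, i1, j1 = _gotoh_kernel(
        _encode(read_seq),
        _encode(ref_seq),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    cols = ["I"] * i0 + [_OP_CHARS[o] for o in ops[::-1]] + ["I"] * (len(read_seq) - i1)
    return int(score), cols, int(j0), int(j1)


def left_align_indels(
    cols: list[str], read_seq: str, ref_seq: str, ref_start: int
) -> list[str]:
    """Shift indel runs to their leftmost equivalent placement.

    A deletion run may hop over a preceding match column when the reference
    base entering the run equals the one leaving it; an insertion run when its
    last read base equals the preceding matched reference base.  Mismatch
    columns block shifting, keeping the edit script score-invariant.
    """
    # explicit per-column (op, read_idx, ref_idx) triples
    triples: list[tuple[str, int, int]] = []
    i, j = 0, ref_start
    for op in cols:
        if op in "MX":
            triples.append((op, i, j))
            i += 1
            j += 1
        elif op == "I":
            triples.append((op, i, -1))
            i += 1
        else:
            triples.append((op, -1, j))
            j += 1

    c = 0
    while c < len(triples):
        op = triples[c][0]
        if op not in "ID" or (c > 0 and triples[c - 1][0] == op):
            c += 1
            continue
        e = c
        while e < len(triples) and triples[e][0] == op:
            e += 1
        k = e - c
        while c > 0 and triples[c - 1][0] == "M":
            pm = triples[c - 1]
            if op == "D":
                p = triples[c][2]
                if ref_seq[p - 1] != ref_seq[p + k - 1]:
                    break
                run = [("D", -1, p - 1 + t) for t in range(k)]
                newm = ("M", pm[1], p + k - 1)
            else:
                i0 = triples[c][1]
                p = pm[2]
                if read_seq[i0 + k - 1] != ref_seq[p]:
                    break
                run = [("I", i0 - 1 + t, -1) for t in range(k)]
                newm = ("M", i0 + k - 1, p)
            triples[c - 1 : e] = run + [newm]
            c -= 1
            e -= 1
        c = e + 1
    return [t[0] for t in triples]


def _rle(cols: list[str]) -> list[tuple[str, int]]:
    names = {"M": "match", "X": "mismatch", "I": "insertion", "D": "deletion"}
    out: list[tuple[str, int]] = []
    for op in cols:
        name = names[op]
        if out and out[-1][0] == name:
            out[-1] = (name, out[-1][1] + 1)
        else:
            out.append((name, 1))
    return out


def align_to_reference(
    read: StrandRead, amplicon: Amplicon, scoring: Scoring = Scoring()
) -> AlignedStrand:
    """Align a strand consensus read to its reference amplicon.

    First-strand reads are reverse-complemented into reference frame first
    and flagged.  Internal alignments get the sentinel mapping quality; use
    :func:`read_sam` to import externally aligned reads instead.
    """
    if read.strand == "first":
        seq = revcomp(read.sequence)
        quals = np.asarray(read.qualities)[::-1].copy()
        orientation = "reverse-complemented"
    else:
        seq = read.sequence
        quals = np.asarray(read.qualities).copy()
        orientation = "as-is"
    score, cols, ref_start, ref_end = align_semiglobal(seq, amplicon.sequence, scoring)
    if score < scoring.min_score_per_base * len(seq):
        raise AlignmentError(
            f"alignment score {score} below floor for read {read.molecule_id}"
        )
    cols = left_align_indels(cols, seq, amplicon.sequence, ref_start)
    return AlignedStrand(
        read=read,
        sequence=seq,
        qualities=quals,
        oplist=_rle(cols),
        ref_start=ref_start,
        ref_end=ref_end,
        mapping_quality=Scoring.MAPQ_SENTINEL,
        orientation=orientation,
        supplementary_count=0,
        score=score,
    )


def apply_read_filters(
    aligned: AlignedStrand,
    amplicon: Amplicon,
    expected_len: int | None = None,
    min_mapq: int = 60,
    max_len_dev: int = 50,
) -> FilterDecision:
    """Read-level filter cascade; the first failing rule is recorded.

    Rules, in fixed order: mapping quality below *min_mapq*; alignment not
    starting within the 5'-primer region; not ending within the 3'-primer
    region; split (chimeric) mapping; read length deviating from the expected
    length by more than *max_len_dev* bases.  All boundaries are inclusive.
    """
    expected = len(amplicon.sequence) if expected_len is None else expected_len
    if aligned.mapping_quality < min_mapq:
        return FilterDecision(False, "mapq")
    p5s, p5e = amplicon.primer5
    if not (p5s <= aligned.ref_start < p5e):
        return FilterDecision(False, "span_5prime")
    p3s, p3e = amplicon.primer3
    if not (p3s < aligned.ref_end <= p3e):
        return FilterDecision(False, "span_3prime")
    if aligned.supplementary_count > 0:
        return FilterDecision(False, "chimera")
    if abs(len(aligned.sequence) - expected) > max_len_dev:
        return FilterDecision(False, "length")
    return FilterDecision(True)


# ---------------------------------------------------------------------------
# SAM I/O (pysam)

_CIGAR_CODE = {"match": 7, "mismatch": 8, "insertion": 1, "deletion": 2}


def write_sam(alignments: list[AlignedStrand], amplicon: Amplicon, path: str | Path) -> None:
    """Write alignments as SAM (=/X/I/D CIGAR; np and st tags)."""
    import pysam

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": amplicon.id, "LN": len(amplicon.sequence)}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"{a.read.molecule_id}|{a.read.strand}"
            seg.query_sequence = a.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in a.qualities)
            )
            seg.reference_id = 0
            seg.reference_start = a.ref_start
            seg.mapping_quality = a.mapping_quality
            seg.cigartuples = [(_CIGAR_CODE[op], k) for op, k in a.oplist]
            seg.flag = 0x10 if a.orientation == "reverse-complemented" else 0
            seg.set_tag("np", a.read.n_passes, "i")
            seg.set_tag("st", a.read.strand, "Z")
            fh.write(seg)


def read_sam(path: str | Path, amplicon: Amplicon) -> list[AlignedStrand]:
    """Import external alignments from SAM/BAM.

    M CIGAR ops are resolved into match/mismatch against the reference; soft
    clips become terminal insertions.  Supplementary records (flag 0x800) are
    counted onto their primary record rather than returned.
    """
    import pysam

    supp: dict[str, int] = {}
    primaries = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            if seg.is_supplementary:
                supp[seg.query_name] = supp.get(seg.query_name, 0) + 1
            else:
                primaries.append(seg.to_dict() | {"_seg": seg})

    out: list[AlignedStrand] = []
    for rec in primaries:
        seg = rec["_seg"]
        seq = seg.query_sequence or ""
        quals = (
            np.array(seg.query_qualities, dtype=np.int16)
            if seg.query_qualities is not None
            else np.zeros(len(seq), dtype=np.int16)
        )
        cols: list[str] = []
        i, j = 0, seg.reference_start
        for code, k in seg.cigartuples or []:
            if code in (0, 7, 8):  # M/=/X resolved against the reference
                for t in range(k):
                    cols.append("M" if seq[i + t] == amplicon.sequence[j + t] else "X")
                i += k
                j += k
            elif code in (1, 4):  # I and S both consume read
                cols.extend("I" * k)
                i += k
            elif code == 2:
                cols.extend("D" * k)
                j += k
            elif code == 5:  # hard clip: bases absent from SEQ
                continue
            else:
                raise ValueError(f"unsupported CIGAR op code {code}")
        name = seg.query_name
        mid, _, strand = name.partition("|")
        strand = seg.get_tag("st") if seg.has_tag("st") else (strand or "second")
        n_passes = int(seg.get_tag("np")) if seg.has_tag("np") else 1
        orientation = "reverse-complemented" if seg.is_reverse else "as-is"
        native_seq = revcomp(seq) if orientation == "reverse-complemented" else seq
        native_quals = quals[::-1].copy() if orientation == "reverse-complemented" else quals
        read = StrandRead(mid, strand, native_seq, native_quals, n_passes)
        cols = left_align_indels(cols, seq, amplicon.sequence, seg.reference_start)
        out.append(
            AlignedStrand(
                read=read,
                sequence=seq,
                qualities=quals,
                oplist=_rle(cols),
                ref_start=seg.reference_start,
                ref_end=seg.reference_end,
                mapping_quality=seg.mapping_quality,
                orientation=orientation,
                supplementary_count=supp.get(name, 0),
            )
        )
    return out
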