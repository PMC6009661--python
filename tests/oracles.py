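"""Independent oracles used by the test suite.

These deliberately re-derive expected values by brute force or closed form,
separately from the implementation paths they check.
"""
from __future__ import annotations

import math
from functools import lru_cache


def bruteforce_overlap_score(read: str, ref: str, match=2, mismatch=-4, gap_open=-6, gap_extend=-1) -> int:
    """Optimal overlap-alignment score by exhaustive recursion with memo.

    Affine gaps (a gap of length k costs open + k*extend); terminal gaps on
    either sequence are free.  Independent of the production DP kernel.
    """
    m, n = len(read), len(ref)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        # best score aligning read[i:] vs ref[j:], given the previous column
        # state ('H' aligned, 'I' in read-gap run, 'D' in ref-gap run)
        if i == m or j == n:
            return 0.0  # trailing gaps are free
        options = []
        s = match if read[i] == ref[j] else mismatch
        options.append(s + best(i + 1, j + 1, "H"))
        open_d = gap_extend if state == "D" else gap_open + gap_extend
        options.append(open_d + best(i, j + 1, "D"))
        open_i = gap_extend if state == "I" else gap_open + gap_extend
        options.append(open_i + best(i + 1, j, "I"))
        return max(options)

    starts = [(i, 0) for i in range(m + 1)] + [(0, j) for j in range(n + 1)]
    return int(max(best(i, j, "H") for i, j in starts))


def phred_agreement(f: float) -> int:
    """Closed-form Phred from column agreement, capped at 93."""
    return int(min(93, round(-10 * math.log10(max(1 - f, 10**-9.3)))))


def welch_t(a, b) -> tuple[float, float]:
    """Textbook Welch t statistic and degrees of freedom."""
    import statistics

    ma, mb = statistics.fmean(a), statistics.fmean(b)
    va, vb = statistics.variance(a), statistics.variance(b)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    dof = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, dof


def enumerate_substitution_classes() -> dict[tuple[str, str], tuple[str, str]]:
    """All 12 (reference base, observed cDNA base) mismatches with their
    equivalent RNAP / RT error pairs, derived from the pairing rules alone.

    An RNAP error rX->rY puts RNA base Y at a reference-X position; the
    reverse transcriptase then pairs it correctly, so the cDNA shows the
    Watson-Crick complement of Y.  An RT error dP->dQ happens where the RNA
    (reference) base is the complement of P and the cDNA shows Q.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rna = {"A": "A", "C": "C", "G": "G", "T": "U"}
    table = {}
    for ref in "ACGT":
        for cdna in "ACGT":
            if cdna == comp[ref]:
                continue
            rnap_prod = comp[cdna]  # RNA base whose correct copy is `cdna`
            rt_template = comp[ref]  # expected cDNA base opposite the RNA
            table[(ref, cdna)] = (
                f"r{rna[ref]}->r{rna[rnap_prod]}",
                f"d{rt_template}->d{cdna}",
            )
    return table
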