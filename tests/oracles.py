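"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment scores come
from exhaustive enumeration of every global alignment, and N50/L50 from a
plain cumulative loop.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")


def blosum62_score(x: str, y: str) -> float:
    if x == "X" or y == "X":
        return 0.0
    return float(_BLOSUM[x, y])


def enumerate_global_alignment_score(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0
) -> float:
    """Maximum score over ALL global alignments of a and b (affine gaps).

    A gap run of length L costs gap_open + (L-1)*gap_extend per sequence.
    Exponential enumeration; feasible for len <= ~7.
    """
    best = [float("-inf")]

    def rec(i: int, j: int, prev: str | None, score: float) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + blosum62_score(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "D", score - (gap_extend if prev == "D" else gap_open))
        if j < len(b):
            rec(i, j + 1, "I", score - (gap_extend if prev == "I" else gap_open))

    rec(0, 0, None, 0.0)
    return best[0]


def n50_l50_oracle(lengths) -> tuple[int, int]:
    """N50/L50 by a plain cumulative-sum loop over descending lengths."""
    total = sum(lengths)
    acc = 0
    for i, L in enumerate(sorted(lengths, reverse=True), start=1):
        acc += L
        if 2 * acc >= total:
            return L, i
    raise AssertionError("unreachable for non-empty input")
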