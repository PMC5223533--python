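"""Independent brute-force oracles used to check the implementation.

These deliberately take the dumbest correct route — per-base painting,
exhaustive enumeration, exact rational arithmetic — and share no code with
the package's interval/stats machinery.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

# label codes for the per-base array
LABEL_CODES = {"exon": 0, "intron": 1, "upstream": 2, "downstream": 3, "intergenic": 4}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}


def per_base_labels(genes, chrom: str, chrom_len: int, flank_bp: int) -> np.ndarray:
    """Label every base by painting in reverse precedence order.

    intergenic < downstream < upstream < intron (gene span) < exon, so the
    last paint wins and upstream beats downstream, gene bodies beat flanks,
    exons beat everything.
    """
    arr = np.full(chrom_len, LABEL_CODES["intergenic"], dtype=np.int8)
    here = [g for g in genes if g.span.chrom == chrom]
    for g in here:  # downstream flanks first (lowest paint)
        lo, hi = _flank(g, chrom_len, flank_bp, upstream=False)
        arr[lo:hi] = LABEL_CODES["downstream"]
    for g in here:
        lo, hi = _flank(g, chrom_len, flank_bp, upstream=True)
        arr[lo:hi] = LABEL_CODES["upstream"]
    for g in here:
        arr[g.span.start : g.span.end] = LABEL_CODES["intron"]
    for g in here:
        for ex in g.exons:
            arr[ex.start : ex.end] = LABEL_CODES["exon"]
    return arr


def _flank(g, chrom_len: int, flank_bp: int, upstream: bool) -> tuple[int, int]:
    left = (max(0, g.span.start - flank_bp), g.span.start)
    right = (g.span.end, min(chrom_len, g.span.end + flank_bp))
    if g.span.strand == "-":
        return right if upstream else left
    return left if upstream else right


def per_base_overlaps(arr: np.ndarray, start: int, end: int) -> dict[str, int]:
    """bp of each label covered by [start, end) of the per-base array."""
    counts = np.bincount(arr[start:end], minlength=5)
    return {CODE_LABELS[i]: int(counts[i]) for i in range(5)}


def per_base_primary(arr: np.ndarray, start: int, end: int) -> str:
    """argmax-overlap label with the precedence tie-break."""
    overlaps = per_base_overlaps(arr, start, end)
    best = max(overlaps.values())
    for label in ("exon", "intron", "upstream", "downstream", "intergenic"):
        if overlaps[label] == best:
            return label
    raise AssertionError("unreachable")


def fisher_two_sided(table) -> float:
    """Exhaustive two-sided Fisher p by probability-mass ordering.

    Exact rational arithmetic over all tables sharing the observed margins.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    if denom == 0:
        return 1.0

    def prob(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        pk = prob(k)
        if pk <= p_obs:
            total += pk
    return float(min(Fraction(1), total))


def bh_step_up(p_values) -> list[float]:
    """Hand Benjamini–Hochberg: sort, scale by m/rank, enforce monotone."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = p_values[i] * m / rank_from_top
        running_min = min(running_min, val)
        q[i] = min(1.0, running_min)
    return q


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n), rational arithmetic."""
    denom = comb(N, n)
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return float(min(Fraction(1), total))
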