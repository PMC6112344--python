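"""Independent oracles used across the test suite.

These deliberately share no code with the package: alignment is checked by
a full sliding-window scan, and the binomial CDF by exact integer
arithmetic over rational error probabilities.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def naive_hits(
    query: str,
    entries: list[tuple[str, str]],
    max_mismatch: int,
    both_strands: bool = True,
) -> set[tuple[str, int, str, int]]:
    """Every placement with <= max_mismatch substitutions, by full scan.

    Returns {(ref_id, 1-based start, strand, n_mismatch)}; an N in the
    reference counts as a mismatch against any read base.
    """
    hits: set[tuple[str, int, str, int]] = set()
    strands = ("+", "-") if both_strands else ("+",)
    for ref_id, ref in entries:
        ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
        for strand in strands:
            oriented = query if strand == "+" else rc(query)
            L = len(oriented)
            if len(ref) < L:
                continue
            q_arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
            windows = sliding_window_view(ref_arr, L)
            bad = ((windows != q_arr) | (windows == ord("N"))).sum(axis=1)
            for off in np.nonzero(bad <= max_mismatch)[0]:
                hits.add((ref_id, int(off) + 1, strand, int(bad[off])))
    return hits


def exact_binomial_cdf(k: int, n: int, p_err: Fraction) -> Fraction:
    """P(X <= k) for X ~ Binomial(n, 1 - p_err), by exact term summation."""
    q = 1 - p_err
    return sum(
        Fraction(comb(n, i)) * q**i * p_err ** (n - i) for i in range(k + 1)
    )
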