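"""Small interval-arithmetic helpers shared across modules.

All inputs are 0-based half-open ``(start, end)`` pairs on one chromosome.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np


def merge_intervals(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted list of disjoint intervals."""
    pairs = sorted((int(a), int(b)) for a, b in pairs)
    merged: list[tuple[int, int]] = []
    for a, b in pairs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def union_length(pairs: Iterable[tuple[int, int]]) -> int:
    return sum(b - a for a, b in merge_intervals(pairs))


def overlap_length(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    """Total nucleotides in (union of a) intersect (union of b).

    Each nucleotide is counted at most once however many input intervals
    cover it.
    """
    ma, mb = merge_intervals(a), merge_intervals(b)
    i = j = 0
    total = 0
    while i < len(ma) and j < len(mb):
        lo = max(ma[i][0], mb[j][0])
        hi = min(ma[i][1], mb[j][1])
        if lo < hi:
            total += hi - lo
        if ma[i][1] <= mb[j][1]:
            i += 1
        else:
            j += 1
    return total


def covered_mask(pairs: Iterable[tuple[int, int]], start: int, end: int) -> np.ndarray:
    """Boolean per-base membership over [start, end); brute-force oracle helper."""
    mask = np.zeros(end - start, dtype=bool)
    for a, b in pairs:
        lo, hi = max(a, start), min(b, end)
        if lo < hi:
            mask[lo - start:hi - start] = True
    return mask
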