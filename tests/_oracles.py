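"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own code paths: the Poisson tail is
a direct partial sum of the pmf, and the peak scan tests every window by
definition and merges with an explicit loop.
"""

from __future__ import annotations

import bisect
import math


def poisson_upper_tail(count: int, lam: float) -> float:
    """P(X >= count) by direct summation of the pmf from ``count`` upward."""
    if count == 0:
        return 1.0
    if lam == 0:
        return 0.0
    log_term = -lam + count * math.log(lam) - math.lgamma(count + 1)
    term = math.exp(log_term)
    total = 0.0
    i = count
    while True:
        total += term
        i += 1
        term *= lam / i
        if term < total * 1e-18 and i > count + 5:
            break
        if i > count + 1_000_000:  # pragma: no cover - safety valve
            break
    return min(total, 1.0)


def brute_force_peaks(
    read_starts: list[int],
    chrom_length: int,
    genome_read_total: int,
    genome_length: int,
    window: int = 200,
    step: int = 50,
    alpha: float = 1e-5,
    min_length: int = 200,
    merge_gap: int = 100,
) -> list[tuple[int, int]]:
    """Definitional peak scan: every window tested, merged by distance."""
    lam = genome_read_total * window / genome_length
    starts = sorted(read_starts)
    significant: list[tuple[int, int]] = []
    ws = 0
    while ws < chrom_length:
        we = min(ws + window, chrom_length)
        c = bisect.bisect_left(starts, we) - bisect.bisect_left(starts, ws)
        if c > 0:
            p = 0.0 if lam == 0 else poisson_upper_tail(c, lam)
            if p < alpha:
                significant.append((ws, we))
        ws += step
    merged: list[list[int]] = []
    for s, e in significant:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_length]


def overlap_1bp(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Half-open interval overlap by at least one base."""
    return a[0] < b[1] and b[0] < a[1]
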