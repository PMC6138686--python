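"""Independent brute-force oracles used to check the implementation.

These deliberately use different algorithms from the package: exact
rational arithmetic for the hypergeometric tail, and per-base membership
run-length encoding for locus segmentation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by exact enumeration of the hypergeometric pmf."""
    total = comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += comb(K, i) * comb(N - K, n - i)
    return Fraction(acc, total)


def segment_by_base(cnvs) -> list[tuple[str, int, int, frozenset[str]]]:
    """Per-base covering-set oracle: run-length encode base-wise CNV sets.

    Only usable for small coordinates; returns (chrom, start, end, cnv_ids)
    runs with non-empty cover, sorted by position.
    """
    by_chrom: dict[str, list] = {}
    for c in cnvs:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    runs = []
    for chrom in sorted(by_chrom):
        recs = by_chrom[chrom]
        lo = min(r.interval.start for r in recs)
        hi = max(r.interval.end for r in recs)
        prev: frozenset[str] | None = None
        run_start = lo
        for pos in range(lo, hi + 1):
            cover = frozenset(
                r.cnv_id for r in recs
                if r.interval.start <= pos < r.interval.end
            ) if pos < hi else frozenset()
            if cover != prev:
                if prev:
                    runs.append((chrom, run_start, pos, prev))
                prev = cover
                run_start = pos
    return runs
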