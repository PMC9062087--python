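"""Comparison of chromatin-loop sets between two conditions.

A loop in one set is *shared* when a single partner loop in the other set
matches BOTH of its anchors, each within a bin tolerance; matching is
one-to-one, greedy by total anchor distance.  Everything unmatched is a
condition-specific loop.  An alternative anchor-wise mode treats a loop as
shared when each of its anchors appears somewhere in the other set,
irrespective of pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .contact_io import GeneRecord, Loop

__all__ = [
    "LoopComparison",
    "LoopLengthStats",
    "specific_loops",
    "loop_length_stats",
    "genes_at_anchors",
    "anchor_intervals",
]

LOOP_RESOLUTION = 10_000  # default anchor width (bp) of the loop calls


def _anchor_bins(loop: Loop, resolution: int) -> tuple[int, int]:
    return (loop.start1 // resolution, loop.start2 // resolution)


@dataclass
class LoopComparison:
    shared: tuple[tuple[Loop, Loop], ...]  # (from a, from b)
    specific_a: tuple[Loop, ...]
    specific_b: tuple[Loop, ...]
    tolerance: int
    resolution: int

    def counts_by_chrom(self) -> dict[str, dict[str, int]]:
        chroms = sorted(
            {l.chrom for l, _ in self.shared}
            | {l.chrom for l in self.specific_a}
            | {l.chrom for l in self.specific_b}
        )
        out = {}
        for c in chroms:
            sh = sum(1 for l, _ in self.shared if l.chrom == c)
            sa = sum(1 for l in self.specific_a if l.chrom == c)
            sb = sum(1 for l in self.specific_b if l.chrom == c)
            out[c] = {
                "shared": sh,
                "specific_a": sa,
                "specific_b": sb,
                "specific_fraction_a": sa / (sh + sa) if sh + sa else float("nan"),
                "specific_fraction_b": sb / (sh + sb) if sh + sb else float("nan"),
            }
        return out


def specific_loops(
    a: Sequence[Loop],
    b: Sequence[Loop],
    tolerance: int = 0,
    resolution: int = LOOP_RESOLUTION,
    mode: str = "joint",
) -> LoopComparison:
    """Split two loop sets into shared and condition-specific loops.

    ``mode="joint"`` (default): a loop is shared only if one partner loop
    matches both anchors, each within ± ``tolerance`` bins of ``resolution``
    bp; pairing is one-to-one, greedy by total anchor distance.
    ``mode="anchorwise"``: a loop is shared when each anchor individually
    occurs (within tolerance) among the other set's anchors.
    """
    if mode not in ("joint", "anchorwise"):
        raise ValueError("mode must be 'joint' or 'anchorwise'")

    if mode == "anchorwise":
        def anchors_of(loops: Sequence[Loop]) -> list[tuple[str, int]]:
            out = []
            for lp in loops:
                b1, b2 = _anchor_bins(lp, resolution)
                out.extend([(lp.chrom, b1), (lp.chrom, b2)])
            return out

        def is_shared(lp: Loop, pool: list[tuple[str, int]]) -> bool:
            b1, b2 = _anchor_bins(lp, resolution)
            near = lambda x: any(c == lp.chrom and abs(p - x) <= tolerance for c, p in pool)
            return near(b1) and near(b2)

        pool_b = anchors_of(b)
        pool_a = anchors_of(a)
        spec_a = tuple(lp for lp in a if not is_shared(lp, pool_b))
        spec_b = tuple(lp for lp in b if not is_shared(lp, pool_a))
        shared_a = [lp for lp in a if lp not in spec_a]
        shared_b = [lp for lp in b if lp not in spec_b]
        # anchor-wise sharing has no pairing; zip truncates to the shorter side
        shared = tuple(zip(shared_a, shared_b))
        return LoopComparison(shared, spec_a, spec_b, tolerance, resolution)

    candidates: list[tuple[int, int, int]] = []  # (total distance, ia, ib)
    for ia, la in enumerate(a):
        ba1, ba2 = _anchor_bins(la, resolution)
        for ib, lb in enumerate(b):
            if la.chrom != lb.chrom:
                continue
            bb1, bb2 = _anchor_bins(lb, resolution)
            d1, d2 = abs(ba1 - bb1), abs(ba2 - bb2)
            if d1 <= tolerance and d2 <= tolerance:
                candidates.append((d1 + d2, ia, ib))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared: list[tuple[Loop, Loop]] = []
    for _, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        shared.append((a[ia], b[ib]))
    spec_a = tuple(lp for i, lp in enumerate(a) if i not in used_a)
    spec_b = tuple(lp for i, lp in enumerate(b) if i not in used_b)
    return LoopComparison(tuple(shared), spec_a, spec_b, tolerance, resolution)


class LoopLengthStats(NamedTuple):
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float


def loop_length_stats(a: Sequence[Loop], b: Sequence[Loop]) -> LoopLengthStats:
    """Loop-length summary and a two-sided rank-sum test between two sets."""
    if not a or not b:
        raise ValueError("both loop sets must be nonempty")
    la = np.array([lp.length for lp in a])
    lb = np.array([lp.length for lp in b])
    res = mannwhitneyu(la, lb, alternative="two-sided", method="asymptotic")
    return LoopLengthStats(
        float(np.median(la)),
        float(np.median(lb)),
        float(la.mean()),
        float(lb.mean()),
        float(res.statistic),
        float(res.pvalue),
    )


def anchor_intervals(loops: Iterable[Loop]) -> list[tuple[str, int, int]]:
    """All anchor intervals (chrom, start, end) of a loop collection."""
    out = []
    for lp in loops:
        out.append((lp.chrom, lp.start1, lp.end1))
        out.append((lp.chrom, lp.start2, lp.end2))
    return out


def genes_at_anchors(
    loops: Sequence[Loop], genes: Sequence[GeneRecord]
) -> list[tuple[GeneRecord, bool]]:
    """Flag genes whose interval overlaps any loop anchor (>= 1 bp, half-open)."""
    anchors = anchor_intervals(loops)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in anchors:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for g in genes:
        hit = any(g.start < e and s < g.end for s, e in by_chrom.get(g.chrom, ()))
        out.append((g, hit))
    return out
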