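"""Translocation hotspot detection, WGS double-confirmation, and SV overlap.

Inter-chromosomal rearrangements show up in a Hi-C map as rectangular
blocks of elevated trans signal.  The scan smooths each trans block with a
box filter, takes the connected regions that rise above half the required
fold over the background (the median per-entry level estimated from row
means, robust to the hotspot itself), refines each region's edges at
half-height against the partner span, and keeps blocks whose mean entry is
at least ``fold_threshold`` times the background.

A candidate becomes *double-confirmed* when at least one of its four span
edges, widened by an edge tolerance, contains the corresponding-chromosome
position of a WGS breakpoint.  Confirmed blocks can be masked out of the
matrix so downstream analyses ignore rearranged signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp

from .contact_io import Breakpoint, ContactMatrix, SvInterval
from .stats import pearson_chi2

__all__ = [
    "TranslocationEvent",
    "SvOverlapResult",
    "trans_hotspot_scan",
    "scan_all_pairs",
    "double_confirm",
    "mask_events",
    "sv_overlap_enrichment",
]


@dataclass(frozen=True)
class TranslocationEvent:
    chrom_a: str
    start_a: int  # bp, half-open span on chrom_a
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    block_mean: float
    background: float
    status: str = "candidate"  # "candidate" | "double-confirmed"
    breakpoints: tuple[Breakpoint, ...] = ()

    @property
    def fold(self) -> float:
        return self.block_mean / self.background if self.background > 0 else float("inf")


# ---------------------------------------------------------------------------
# Hotspot detection


def _smooth1d(x: np.ndarray, window: int = 3) -> np.ndarray:
    return ndi.uniform_filter1d(x, size=max(window, 1), mode="nearest")


def _refine_edges(profile: np.ndarray, lo: int, hi: int, bg: float) -> tuple[int, int]:
    """Snap segment edges to the half-height run of the (smoothed) profile."""
    prof = _smooth1d(profile, 3)
    level = prof[lo:hi].mean()
    if level <= bg:
        return lo, hi
    half = bg + (level - bg) / 2
    above = prof >= half
    # maximal run of `above` overlapping [lo, hi)
    best = (lo, hi)
    i = 0
    n = len(prof)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if i < hi and j > lo:  # overlaps
                best = (i, j)
                if j >= hi:
                    break
            i = j
        else:
            i += 1
    return best


def trans_hotspot_scan(
    m: ContactMatrix,
    chrom_a: str,
    chrom_b: str,
    fold_threshold: float = 4.0,
    min_span: int = 10,
) -> list[TranslocationEvent]:
    """Scan one inter-chromosomal block for translocation hotspots.

    The per-entry background is the median of the row means (robust to the
    hotspot, and well defined on sparse count matrices).  Candidate
    regions are connected components of the box-smoothed block above
    ``fold_threshold / 2`` times background; edges are then refined at
    half-height on row/column profiles restricted to the partner span, and
    blocks keep only if their raw mean entry reaches the full fold.
    """
    x = m.trans_block(chrom_a, chrom_b)
    if not (x > 0).any():
        return []
    alo, ahi = m.bins.chrom_range(chrom_a)
    blo, bhi = m.bins.chrom_range(chrom_b)
    row_ok = ~m.mask[alo:ahi]
    col_ok = ~m.mask[blo:bhi]
    if not (row_ok.any() and col_ok.any()):
        return []

    bg = float(np.median(x[row_ok][:, col_ok].mean(axis=1)))
    if bg <= 0:
        bg = float(x[row_ok][:, col_ok].mean())
    if bg <= 0:
        return []

    # masked rows/cols are unknown signal, not absence: fill with background
    # so they neither split candidate regions nor break half-height runs
    x_fill = x.copy()
    x_fill[~row_ok, :] = bg
    x_fill[:, ~col_ok] = bg

    k = max(3, min_span)
    smoothed = ndi.uniform_filter(x_fill, size=k, mode="nearest")
    # candidate threshold: half the required fold, but never below the
    # noise floor of the smoothed field (median + 6 robust sigma)
    med_s = float(np.median(smoothed))
    sigma_s = 1.4826 * float(np.median(np.abs(smoothed - med_s)))
    thr = max((fold_threshold / 2) * bg, med_s + 6 * sigma_s)
    labeled, _ = ndi.label(smoothed >= thr)

    boxes = [
        [sl[0].start, sl[0].stop, sl[1].start, sl[1].stop]
        for sl in ndi.find_objects(labeled)
    ]

    def try_merge(items: list[list[int]], gap: int) -> list[list[int]]:
        out: list[list[int]] = []
        for cand in sorted(map(tuple, items)):
            placed = False
            for blk in out:
                if (cand[0] < blk[1] + gap and blk[0] < cand[1] + gap
                        and cand[2] < blk[3] + gap and blk[2] < cand[3] + gap):
                    blk[0] = min(blk[0], cand[0])
                    blk[1] = max(blk[1], cand[1])
                    blk[2] = min(blk[2], cand[2])
                    blk[3] = max(blk[3], cand[3])
                    placed = True
                    break
            if not placed:
                out.append(list(cand))
        return out

    # a masked stripe can split one hotspot: merge boxes within the filter size
    boxes = try_merge(boxes, k)

    def masked_mean(arr2d: np.ndarray, rows: slice, cols: slice, axis: int) -> np.ndarray:
        """Profile over unmasked partner cells, masked positions interpolated."""
        sub_ok = col_ok[cols] if axis == 1 else row_ok[rows]
        if axis == 1:
            prof = x[:, cols][:, sub_ok].mean(axis=1) if sub_ok.any() else x[:, cols].mean(axis=1)
            own_ok = row_ok
        else:
            prof = x[rows, :][sub_ok, :].mean(axis=0) if sub_ok.any() else x[rows, :].mean(axis=0)
            own_ok = col_ok
        if (~own_ok).any() and own_ok.any():
            idx = np.arange(len(prof))
            prof = prof.copy()
            prof[~own_ok] = np.interp(idx[~own_ok], idx[own_ok], prof[own_ok])
        return prof

    candidates: list[tuple[int, int, int, int]] = []
    for rlo, rhi, clo, chi_ in boxes:
        if rhi - rlo < min_span or chi_ - clo < min_span:
            continue
        # refine each axis against the partner span, where signal is strong
        rlo2, rhi2 = _refine_edges(masked_mean(x, slice(rlo, rhi), slice(clo, chi_), 1), rlo, rhi, bg)
        clo2, chi2_ = _refine_edges(masked_mean(x, slice(rlo2, rhi2), slice(clo, chi_), 0), clo, chi_, bg)
        if rhi2 - rlo2 < min_span or chi2_ - clo2 < min_span:
            continue
        cells = np.outer(row_ok[rlo2:rhi2], col_ok[clo2:chi2_])
        block = x[rlo2:rhi2, clo2:chi2_]
        mean_entry = block[cells].mean() if cells.any() else block.mean()
        if mean_entry >= fold_threshold * bg:
            candidates.append((rlo2, rhi2, clo2, chi2_))

    merged = try_merge([list(c) for c in candidates], 0)

    res = m.bins.resolution
    alo, _ = m.bins.chrom_range(chrom_a)
    blo, _ = m.bins.chrom_range(chrom_b)
    len_a = m.bins.genome.length_of(chrom_a)
    len_b = m.bins.genome.length_of(chrom_b)
    events = []
    for rlo, rhi, clo, chi_ in merged:
        events.append(
            TranslocationEvent(
                chrom_a,
                rlo * res,
                min(rhi * res, len_a),
                chrom_b,
                clo * res,
                min(chi_ * res, len_b),
                float(x[rlo:rhi, clo:chi_].mean()),
                bg,
            )
        )
    return events


def scan_all_pairs(m: ContactMatrix, fold_threshold: float = 4.0, min_span: int = 10) -> list[TranslocationEvent]:
    """Scan every chromosome pair of a genome-wide matrix."""
    chroms = m.bins.genome.names
    events: list[TranslocationEvent] = []
    for i in range(len(chroms)):
        for j in range(i + 1, len(chroms)):
            events.extend(trans_hotspot_scan(m, chroms[i], chroms[j], fold_threshold, min_span))
    return events


# ---------------------------------------------------------------------------
# Double confirmation and masking


def _edge_hit(pos: int, edge_bp: int, resolution: int, tol: int) -> bool:
    """Is bp position within the edge bin widened by ± tol bins?"""
    edge_bin = edge_bp // resolution
    pos_bin = pos // resolution
    return abs(pos_bin - edge_bin) <= tol


def double_confirm(
    candidates: list[TranslocationEvent],
    breakpoints: list[Breakpoint],
    resolution: int,
    edge_tolerance: int = 1,
) -> list[TranslocationEvent]:
    """Mark candidates whose span edge (± tolerance bins) contains a WGS breakpoint.

    A breakpoint supports an event when its chromosome pair matches (either
    orientation) and its position on either chromosome falls in one of the
    four edge bins of the event span, widened by ``edge_tolerance`` bins.
    Returns all events with updated status; unconfirmed stay candidates.
    """
    out = []
    for ev in candidates:
        support = []
        for bp in breakpoints:
            if (bp.chrom_a, bp.chrom_b) == (ev.chrom_a, ev.chrom_b):
                pa, pb = bp.pos_a, bp.pos_b
            elif (bp.chrom_b, bp.chrom_a) == (ev.chrom_a, ev.chrom_b):
                pa, pb = bp.pos_b, bp.pos_a
            else:
                continue
            hit = (
                _edge_hit(pa, ev.start_a, resolution, edge_tolerance)
                or _edge_hit(pa, max(ev.end_a - 1, 0), resolution, edge_tolerance)
                or _edge_hit(pb, ev.start_b, resolution, edge_tolerance)
                or _edge_hit(pb, max(ev.end_b - 1, 0), resolution, edge_tolerance)
            )
            if hit:
                support.append(bp)
        if support:
            out.append(replace(ev, status="double-confirmed", breakpoints=tuple(support)))
        else:
            out.append(ev)
    return out


def mask_events(m: ContactMatrix, events: list[TranslocationEvent]) -> ContactMatrix:
    """Remove entries inside confirmed event blocks (cis signal untouched)."""
    confirmed = [ev for ev in events if ev.status == "double-confirmed"]
    if not confirmed:
        return m
    coo = m.data.tocoo()
    drop = np.zeros(coo.nnz, dtype=bool)
    for ev in confirmed:
        alo, _ = m.bins.chrom_range(ev.chrom_a)
        blo, _ = m.bins.chrom_range(ev.chrom_b)
        res = m.bins.resolution
        ra = (alo + ev.start_a // res, alo + (ev.end_a - 1) // res + 1)
        rb = (blo + ev.start_b // res, blo + (ev.end_b - 1) // res + 1)
        for (lo1, hi1), (lo2, hi2) in (((ra), (rb)), ((rb), (ra))):
            drop |= (coo.row >= lo1) & (coo.row < hi1) & (coo.col >= lo2) & (coo.col < hi2)
    keep = ~drop
    data = sp.coo_matrix(
        (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=coo.shape
    ).tocsr()
    return ContactMatrix(m.bins, data, m.kind, m.mask.copy())


# ---------------------------------------------------------------------------
# SV overlap enrichment


@dataclass(frozen=True)
class SvOverlapResult:
    sv_type: str
    fraction_all: float       # affected fraction among all features
    fraction_altered: float   # affected fraction among the altered subset
    table: tuple[tuple[int, int], tuple[int, int]]  # altered/stable x affected/not
    chi2: float
    p_value: float


def _overlaps_any(chrom: str, start: int, end: int, svs: list[SvInterval]) -> bool:
    return any(s.chrom == chrom and start < s.end and s.start < end for s in svs)


def sv_overlap_enrichment(
    features: list[tuple[str, int, int]],
    altered: np.ndarray,
    svs: list[SvInterval],
    sv_types: tuple[str, ...] | None = None,
) -> list[SvOverlapResult]:
    """Per SV type: feature fractions overlapping SVs, all vs altered subset.

    ``features`` are (chrom, start, end) intervals (TAD boundaries or loop
    anchors); ``altered`` is a parallel boolean array marking the
    condition-specific subset.  Fractions mirror the all-vs-altered display;
    the chi-square is computed on the disjoint altered vs non-altered 2x2
    table (Pearson, no continuity correction).
    """
    if not features:
        raise ValueError("empty feature set")
    altered = np.asarray(altered, dtype=bool)
    if altered.shape != (len(features),):
        raise ValueError("altered flags must parallel features")
    if sv_types is None:
        sv_types = tuple(sorted({s.sv_type for s in svs}))
    results = []
    for svt in sv_types:
        pool = [s for s in svs if s.sv_type == svt]
        affected = np.array([_overlaps_any(c, s, e, pool) for c, s, e in features])
        n_alt = int(altered.sum())
        aff_alt = int((affected & altered).sum())
        aff_stable = int((affected & ~altered).sum())
        n_stable = len(features) - n_alt
        table = ((aff_alt, n_alt - aff_alt), (aff_stable, n_stable - aff_stable))
        stat, _, p = pearson_chi2(table)
        results.append(
            SvOverlapResult(
                svt,
                float(affected.mean()),
                float(aff_alt / n_alt) if n_alt else float("nan"),
                table,
                stat,
                p,
            )
        )
    return results
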