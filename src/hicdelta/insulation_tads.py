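"""Insulation scores, TAD boundary calling, and cross-condition comparison.

The insulation score at a bin is the mean contact signal in a w x w square
sliding along the matrix diagonal, normalized per chromosome as
log2(raw / chromosome mean).  Boundaries are valleys of the normalized
score, located as minus-to-plus zero crossings of a delta track (right-window
mean minus left-window mean) and kept when their delta amplitude exceeds a
strength threshold.  TADs are the intervals between consecutive boundaries.

Boundary sets from two conditions are matched greedily (nearest first,
one-to-one, within a bin tolerance); unmatched boundaries are
condition-specific, and a TAD is "altered" when any specific boundary of
either condition touches it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .contact_io import BinTable, ContactMatrix

__all__ = [
    "InsulationTrack",
    "Boundary",
    "BoundarySet",
    "Tad",
    "TadSet",
    "BoundaryComparison",
    "insulation_score",
    "call_boundaries",
    "compare_boundaries",
    "tads_from_boundaries",
    "altered_tads",
    "delta_insulation",
    "tad_size_stats",
    "boundary_precision_recall",
]


@dataclass
class InsulationTrack:
    bins: BinTable
    raw: np.ndarray      # mean-square score, NaN where undefined
    norm: np.ndarray     # log2(raw / chrom mean of raw), NaN where undefined
    window: int

    def valid(self) -> np.ndarray:
        return np.isfinite(self.norm)


def insulation_score(m: ContactMatrix, window: int = 10) -> InsulationTrack:
    """Insulation score with a ``window``-bin square (w >= 2).

    The raw score at bin i is the mean of the entries in the square
    (i-w..i-1) x (i+1..i+w) over unmasked pairs; it is undefined within w
    bins of a chromosome edge, at masked bins, and where the square holds
    no unmasked pair.  Chromosomes shorter than 2w+1 bins are all-NaN.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = m.bins.n_bins
    raw = np.full(n, np.nan)
    norm = np.full(n, np.nan)
    for chrom in m.bins.genome.names:
        lo, hi = m.bins.chrom_range(chrom)
        nc = hi - lo
        if nc < 2 * window + 1:
            continue
        block, mask = m.cis_block(chrom)
        valid_bin = ~mask
        for i in range(window, nc - window):
            if mask[i]:
                continue
            rows = slice(i - window, i)
            cols = slice(i + 1, i + window + 1)
            pair_ok = np.outer(valid_bin[rows], valid_bin[cols])
            if pair_ok.any():
                raw[lo + i] = block[rows, cols][pair_ok].mean()
        chrom_raw = raw[lo:hi]
        defined = np.isfinite(chrom_raw) & (chrom_raw > 0)
        if defined.any():
            mean_raw = chrom_raw[defined].mean()
            norm_c = np.full(nc, np.nan)
            norm_c[defined] = np.log2(chrom_raw[defined] / mean_raw)
            norm[lo:hi] = norm_c
    return InsulationTrack(m.bins, raw, norm, window)


class Boundary(NamedTuple):
    bin: int        # global bin index
    strength: float


@dataclass
class BoundarySet:
    bins: BinTable
    boundaries: tuple[Boundary, ...]  # sorted by bin, unique

    def __post_init__(self) -> None:
        bs = [b.bin for b in self.boundaries]
        if bs != sorted(set(bs)):
            raise ValueError("boundaries must be sorted and unique")

    def __len__(self) -> int:
        return len(self.boundaries)

    def bin_indices(self) -> np.ndarray:
        return np.array([b.bin for b in self.boundaries], dtype=int)

    def for_chrom(self, chrom: str) -> list[Boundary]:
        lo, hi = self.bins.chrom_range(chrom)
        return [b for b in self.boundaries if lo <= b.bin < hi]


def _smooth(norm: np.ndarray, window: int) -> np.ndarray:
    """Centered nan-aware moving average; NaN only where the window is all-NaN."""
    if window <= 1:
        return norm
    half = window // 2
    n = len(norm)
    out = np.full(n, np.nan)
    for i in range(n):
        seg = norm[max(0, i - half) : i + half + 1]
        if np.isfinite(seg).any():
            out[i] = np.nanmean(seg)
    return out


def _delta_track(norm: np.ndarray, d: int) -> np.ndarray:
    """delta(i) = mean(norm[i+1..i+d]) - mean(norm[i-d..i-1]); NaN where undefined.

    Window means ignore isolated NaNs (masked bins); delta is NaN only when
    a window holds no finite value.
    """
    n = len(norm)
    delta = np.full(n, np.nan)
    for i in range(d, n - d):
        right = norm[i + 1 : i + d + 1]
        left = norm[i - d : i]
        if np.isfinite(right).any() and np.isfinite(left).any():
            delta[i] = np.nanmean(right) - np.nanmean(left)
    return delta


def call_boundaries(
    track: InsulationTrack,
    delta_window: int = 2,
    strength_threshold: float = 0.5,
    smooth_window: int = 3,
) -> BoundarySet:
    """Call boundaries as minus-to-plus zero crossings of the delta track.

    The normalized score is first lightly smoothed (``smooth_window``-bin
    centered moving average, as the insulation-tool family does) so
    count-noise wiggles do not generate spurious crossings.  The boundary
    strength is the amplitude of the delta swing across the crossing: the
    nearest local maximum of delta after the crossing minus the nearest
    local minimum before it.  Boundaries weaker than
    ``strength_threshold`` are dropped.
    """
    found: list[Boundary] = []
    for chrom in track.bins.genome.names:
        lo, hi = track.bins.chrom_range(chrom)
        norm = _smooth(track.norm[lo:hi], smooth_window)
        delta = _delta_track(norm, delta_window)
        n = len(delta)
        for i in range(1, n):
            if not (np.isfinite(delta[i]) and np.isfinite(delta[i - 1])):
                continue
            if not (delta[i - 1] < 0 <= delta[i]):
                continue
            # boundary bin: the lower-insulation bin adjacent to the crossing
            b = i if norm[i] <= norm[i - 1] else i - 1
            # nearest local max of delta at/after the crossing
            k = i
            while k + 1 < n and np.isfinite(delta[k + 1]) and delta[k + 1] >= delta[k]:
                k += 1
            high = delta[k]
            # nearest local min of delta before the crossing
            k = i - 1
            while k - 1 >= 0 and np.isfinite(delta[k - 1]) and delta[k - 1] <= delta[k]:
                k -= 1
            low = delta[k]
            strength = float(high - low)
            if strength >= strength_threshold:
                found.append(Boundary(lo + b, strength))
    return BoundarySet(track.bins, tuple(sorted(found)))


class Tad(NamedTuple):
    chrom: str
    start_bin: int  # global bin index, inclusive
    end_bin: int    # global bin index, exclusive
    altered: bool = False

    def size_bp(self, resolution: int) -> int:
        return (self.end_bin - self.start_bin) * resolution


@dataclass
class TadSet:
    bins: BinTable
    tads: tuple[Tad, ...]

    def sizes_bp(self) -> np.ndarray:
        res = self.bins.resolution
        return np.array([t.size_bp(res) for t in self.tads], dtype=float)

    def altered_fraction_by_chrom(self) -> dict[str, float]:
        """Per chromosome: altered TAD length / chromosome length."""
        out = {}
        res = self.bins.resolution
        for chrom in self.bins.genome.names:
            altered_bp = sum(
                t.size_bp(res) for t in self.tads if t.chrom == chrom and t.altered
            )
            out[chrom] = altered_bp / self.bins.genome.length_of(chrom)
        return out


def tads_from_boundaries(bset: BoundarySet) -> TadSet:
    """TADs as intervals between consecutive boundaries of each chromosome."""
    tads: list[Tad] = []
    for chrom in bset.bins.genome.names:
        bs = [b.bin for b in bset.for_chrom(chrom)]
        for a, b in zip(bs, bs[1:]):
            tads.append(Tad(chrom, a, b))
    return TadSet(bset.bins, tuple(tads))


@dataclass
class BoundaryComparison:
    shared: tuple[tuple[Boundary, Boundary], ...]  # (from a, from b)
    specific_a: tuple[Boundary, ...]
    specific_b: tuple[Boundary, ...]
    tolerance: int

    def specific_bins(self) -> set[int]:
        return {b.bin for b in self.specific_a} | {b.bin for b in self.specific_b}


def compare_boundaries(a: BoundarySet, b: BoundarySet, tolerance: int = 1) -> BoundaryComparison:
    """Greedy nearest-first one-to-one matching of boundaries within ± tolerance bins."""
    if not a.bins.same_binning(b.bins):
        raise ValueError("boundary sets are on different bin tables")
    pairs: list[tuple[int, int, int]] = []  # (distance, idx_a, idx_b)
    for ia, ba in enumerate(a.boundaries):
        for ib, bb in enumerate(b.boundaries):
            dist = abs(ba.bin - bb.bin)
            if dist <= tolerance and a.bins.chrom_of(ba.bin) == b.bins.chrom_of(bb.bin):
                pairs.append((dist, ia, ib))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared: list[tuple[Boundary, Boundary]] = []
    for _, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        shared.append((a.boundaries[ia], b.boundaries[ib]))
    spec_a = tuple(bd for i, bd in enumerate(a.boundaries) if i not in used_a)
    spec_b = tuple(bd for i, bd in enumerate(b.boundaries) if i not in used_b)
    return BoundaryComparison(tuple(shared), spec_a, spec_b, tolerance)


def altered_tads(
    tads_a: TadSet, tads_b: TadSet, comparison: BoundaryComparison
) -> tuple[TadSet, TadSet]:
    """Flag TADs touched by any condition-specific boundary (either condition)."""
    specific = comparison.specific_bins()

    def flag(ts: TadSet) -> TadSet:
        out = []
        for t in ts.tads:
            touched = any(t.start_bin <= s <= t.end_bin for s in specific)
            out.append(Tad(t.chrom, t.start_bin, t.end_bin, touched))
        return TadSet(ts.bins, tuple(out))

    return flag(tads_a), flag(tads_b)


def delta_insulation(a: InsulationTrack, b: InsulationTrack) -> np.ndarray:
    """Per-bin b - a normalized-score difference; NaN where either is undefined."""
    if not a.bins.same_binning(b.bins):
        raise ValueError("tracks are on different bin tables")
    return b.norm - a.norm


class SizeStats(NamedTuple):
    median_a: float
    median_b: float
    statistic: float
    p_value: float


def tad_size_stats(sizes_a: Sequence[float], sizes_b: Sequence[float]) -> SizeStats:
    """Median sizes and a two-sided rank-sum (Wilcoxon/Mann-Whitney) test."""
    sa = np.asarray(sizes_a, dtype=float)
    sb = np.asarray(sizes_b, dtype=float)
    if sa.size == 0 or sb.size == 0:
        raise ValueError("both size sets must be nonempty")
    res = mannwhitneyu(sa, sb, alternative="two-sided", method="asymptotic")
    return SizeStats(float(np.median(sa)), float(np.median(sb)), float(res.statistic), float(res.pvalue))


def boundary_precision_recall(
    called: BoundarySet, truth_bins: Sequence[int], tolerance: int = 1
) -> tuple[float, float]:
    """Precision/recall of called boundaries vs truth bin indices at ± tolerance."""
    called_bins = called.bin_indices()
    truth = np.asarray(sorted(truth_bins), dtype=int)
    if called_bins.size == 0:
        return (float("nan"), 0.0 if truth.size else float("nan"))
    hit_called = np.array([np.min(np.abs(truth - c)) <= tolerance if truth.size else False for c in called_bins])
    hit_truth = np.array([np.min(np.abs(called_bins - t)) <= tolerance for t in truth])
    precision = float(hit_called.mean())
    recall = float(hit_truth.mean()) if truth.size else float("nan")
    return precision, recall
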