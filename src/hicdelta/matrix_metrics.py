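"""Matrix balancing and global contact-map metrics.

Implements ICE (iterative correction) matrix balancing, distance-decay
expected values and observed/expected transforms, cis/trans interaction
ratios, cumulative-contact curves, segmented distance-decay-exponent (IDE)
fits, and hierarchical clustering of collapsed inter-chromosome maps.

All operations work on desk-scale matrices and use dense per-chromosome
blocks internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .contact_io import BinTable, ContactMatrix

__all__ = [
    "BiasVector",
    "IceResult",
    "DecayCurve",
    "CisTransResult",
    "ChromosomeClustering",
    "ice_normalize",
    "expected_by_distance",
    "observed_over_expected",
    "oe_block",
    "cis_trans_ratio",
    "decay_curve_and_ide",
    "cumulative_cis_by_distance",
    "chromosome_cluster",
    "IDE_SEGMENTS",
]

#: Genomic-distance segments (bp, half-open (lo, hi]) for the IDE fits:
#: sub-TAD/TAD scale, intermediate, and long-range architecture.
IDE_SEGMENTS: tuple[tuple[float, float], ...] = (
    (1e5, 1e6),
    (1e6, 1e7),
    (1e7, float("inf")),
)


@dataclass
class BiasVector:
    """Per-bin multiplicative biases from balancing; NaN where masked."""

    values: np.ndarray
    mask: np.ndarray  # True = excluded from balancing

    def __post_init__(self) -> None:
        bad = ~self.mask & ~(self.values > 0)
        if bad.any():
            raise ValueError("unmasked biases must be positive")


class IceResult(NamedTuple):
    matrix: ContactMatrix
    bias: BiasVector
    converged: bool
    n_iter: int


def ice_normalize(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    coverage_filter_fraction: float = 0.02,
) -> IceResult:
    """Balance a raw contact matrix by iterative correction (ICE).

    Bins with zero marginal, or with marginal below the
    ``coverage_filter_fraction`` quantile of the nonzero marginals, are
    masked before balancing.  Each iteration divides the matrix by the outer
    product of relative marginals; convergence is declared when the
    coefficient of variation of the unmasked marginals drops below ``tol``.

    The decomposition is ``W_raw[i, j] = b[i] * b[j] * W_norm[i, j]`` up to a
    global scale.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")

    w = m.dense()
    if not np.isfinite(w).all():
        raise ValueError("non-finite values in matrix")
    marg = w.sum(axis=0)
    mask = m.mask | (marg == 0)
    nonzero = marg[marg > 0]
    if nonzero.size:
        # low-coverage filter: below the quantile AND clearly below typical
        # coverage, so an already-balanced matrix is left untouched
        cutoff = min(np.quantile(nonzero, coverage_filter_fraction), 0.5 * np.median(nonzero))
        mask |= marg < cutoff
    if mask.all():
        raise ValueError("all bins masked; cannot balance")
    w[mask, :] = 0.0
    w[:, mask] = 0.0

    n = m.bins.n_bins
    bias = np.ones(n)
    converged = False
    n_iter = 0
    free = ~mask
    for it in range(1, max_iter + 1):
        n_iter = it
        s = w.sum(axis=0)[free]
        mean_s = s.mean()
        if mean_s == 0:
            raise ValueError("zero total signal among unmasked bins")
        if s.var() / mean_s**2 < tol**2:
            converged = True
            break
        delta = np.ones(n)
        delta[free] = s / mean_s
        w /= np.outer(delta, delta)
        bias[free] *= delta[free]

    bias_out = np.where(mask, np.nan, bias)
    norm = ContactMatrix.from_dense(m.bins, w, kind="normalized")
    norm.mask = mask
    return IceResult(norm, BiasVector(bias_out, mask), converged, n_iter)


# ---------------------------------------------------------------------------
# Expected-by-distance / observed-over-expected


def expected_by_distance(m: ContactMatrix, chrom: str) -> np.ndarray:
    """Mean contact over unmasked pairs at each bin distance d on ``chrom``.

    Entry ``d`` is the mean of W[i, i+d] over unmasked i; NaN where no
    unmasked pair exists.
    """
    block, mask = m.cis_block(chrom)
    n = block.shape[0]
    if n == 0:
        raise ValueError(f"no bins on {chrom}")
    valid = ~mask
    e = np.full(n, np.nan)
    for d in range(n):
        pairs = valid[: n - d] & valid[d:]
        if pairs.any():
            e[d] = np.diagonal(block, d)[pairs].mean()
    return e


def oe_block(m: ContactMatrix, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """Dense observed/expected cis block and its local mask.

    O/E is 0 where the expected value is 0 or undefined.
    """
    block, mask = m.cis_block(chrom)
    e = expected_by_distance(m, chrom)
    n = block.shape[0]
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    denom = e[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where((denom > 0) & np.isfinite(denom), block / denom, 0.0)
    oe[mask, :] = 0.0
    oe[:, mask] = 0.0
    return oe, mask


def observed_over_expected(m: ContactMatrix) -> ContactMatrix:
    """Genome-wide matrix with every cis block replaced by O/E (trans zeroed)."""
    n = m.bins.n_bins
    out = np.zeros((n, n))
    for chrom in m.bins.genome.names:
        lo, hi = m.bins.chrom_range(chrom)
        oe, _ = oe_block(m, chrom)
        out[lo:hi, lo:hi] = oe
    res = ContactMatrix.from_dense(m.bins, out, kind="normalized")
    res.mask = m.mask.copy()
    return res


# ---------------------------------------------------------------------------
# cis / trans ratio


class CisTransResult(NamedTuple):
    cis_total: float
    trans_total: float
    trans_fraction: float


def cis_trans_ratio(m: ContactMatrix) -> CisTransResult:
    """Total cis and trans signal and the trans fraction of the map."""
    cis = m.cis_total()
    trans = m.trans_total()
    total = cis + trans
    frac = trans / total if total > 0 else float("nan")
    return CisTransResult(cis, trans, frac)


# ---------------------------------------------------------------------------
# Distance decay / IDE


@dataclass
class DecayCurve:
    """Log-binned contact-vs-distance curve with per-segment power-law fits.

    ``log10_distance``/``log10_contact`` are per-log-bin means of
    log10(distance bp) and log10(mean contact), so an exact power law stays
    exactly linear after binning.  ``exponents`` maps each distance segment
    to (exponent, intercept) or to NaN where the segment holds fewer than
    three curve points.
    """

    edges_bp: np.ndarray
    log10_distance: np.ndarray
    log10_contact: np.ndarray
    segments: tuple[tuple[float, float], ...]
    exponents: list[tuple[float, float]] = field(default_factory=list)

    @property
    def mean_contact(self) -> np.ndarray:
        return 10.0**self.log10_contact

    @property
    def distance_bp(self) -> np.ndarray:
        return 10.0**self.log10_distance

    def exponent_for(self, lo: float, hi: float) -> float:
        for (slo, shi), (exp, _) in zip(self.segments, self.exponents):
            if (slo, shi) == (lo, hi):
                return exp
        raise KeyError(f"no segment ({lo}, {hi}]")


def _pooled_expected(m: ContactMatrix, chroms: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-bin-distance mean contact over chromosomes (d >= 1)."""
    max_n = max(m.bins.chrom_range(c)[1] - m.bins.chrom_range(c)[0] for c in chroms)
    sums = np.zeros(max_n)
    counts = np.zeros(max_n)
    for chrom in chroms:
        block, mask = m.cis_block(chrom)
        n = block.shape[0]
        valid = ~mask
        for d in range(1, n):
            pairs = valid[: n - d] & valid[d:]
            k = pairs.sum()
            if k:
                sums[d] += np.diagonal(block, d)[pairs].sum()
                counts[d] += k
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
    return mean, counts


def decay_curve_and_ide(
    m: ContactMatrix,
    segments: tuple[tuple[float, float], ...] = IDE_SEGMENTS,
    bins_per_decade: int = 16,
    chroms: Sequence[str] | None = None,
) -> DecayCurve:
    """Pooled contact-decay curve with per-segment log-log OLS exponent fits.

    Distances are pooled over chromosomes at one resolution, averaged per
    bin distance (equal weight per distance, so pair counts do not bias the
    fit), then log-binned at ``bins_per_decade``.  Within each segment
    (lo, hi] bp an ordinary least-squares line in log10-log10 space gives
    the distance-decay exponent; segments with fewer than three curve
    points get NaN.
    """
    chroms = list(chroms or m.bins.genome.names)
    mean, _ = _pooled_expected(m, chroms)
    res = m.bins.resolution
    d_bp = np.arange(len(mean), dtype=float) * res
    ok = (np.arange(len(mean)) >= 1) & np.isfinite(mean) & (mean > 0)
    d_bp, mean = d_bp[ok], mean[ok]
    if d_bp.size == 0:
        raise ValueError("empty matrix: no positive contacts off the diagonal")

    lo_edge = np.log10(d_bp.min())
    hi_edge = np.log10(d_bp.max())
    n_edges = max(2, int(np.ceil((hi_edge - lo_edge) * bins_per_decade)) + 1)
    edges = np.logspace(lo_edge, hi_edge, n_edges)
    edges[-1] *= 1 + 1e-12  # include the max distance
    which = np.digitize(d_bp, edges) - 1

    xs, ys = [], []
    for b in range(n_edges - 1):
        sel = which == b
        if sel.any():
            xs.append(np.log10(d_bp[sel]).mean())
            ys.append(np.log10(mean[sel]).mean())
    x = np.asarray(xs)
    y = np.asarray(ys)

    curve = DecayCurve(edges, x, y, tuple(segments))
    for lo, hi in segments:
        sel = (10.0**x > lo) & (10.0**x <= hi)
        if sel.sum() < 3:
            curve.exponents.append((float("nan"), float("nan")))
        else:
            slope, intercept = np.polyfit(x[sel], y[sel], 1)
            curve.exponents.append((float(slope), float(intercept)))
    return curve


class CumulativeCurve(NamedTuple):
    distance_bp: np.ndarray
    cumulative: np.ndarray           # total cis signal within distance <= d
    cumulative_fraction: np.ndarray  # normalized variant, ends at 1


def cumulative_cis_by_distance(m: ContactMatrix, chroms: Sequence[str] | None = None) -> CumulativeCurve:
    """Monotone cumulative cis signal by genomic distance, pooled over chromosomes."""
    chroms = list(chroms or m.bins.genome.names)
    max_n = max(m.bins.chrom_range(c)[1] - m.bins.chrom_range(c)[0] for c in chroms)
    totals = np.zeros(max_n)
    for chrom in chroms:
        block, mask = m.cis_block(chrom)
        n = block.shape[0]
        valid = ~mask
        for d in range(1, n):
            pairs = valid[: n - d] & valid[d:]
            if pairs.any():
                totals[d] += np.diagonal(block, d)[pairs].sum()
    cum = np.cumsum(totals)
    total = cum[-1]
    frac = cum / total if total > 0 else np.zeros_like(cum)
    d_bp = np.arange(max_n, dtype=float) * m.bins.resolution
    return CumulativeCurve(d_bp, cum, frac)


# ---------------------------------------------------------------------------
# Inter-chromosome clustering


@dataclass
class ChromosomeClustering:
    chroms: tuple[str, ...]
    collapsed: np.ndarray    # chrom x chrom mean trans signal, NaN diagonal
    correlation: np.ndarray  # Pearson across rows (pairwise complete)
    linkage: np.ndarray
    leaf_order: tuple[str, ...]

    def partition(self, k: int) -> frozenset[frozenset[str]]:
        """Cut the dendrogram into k clusters, order-independent form."""
        labels = sch.fcluster(self.linkage, k, criterion="maxclust")
        groups: dict[int, set[str]] = {}
        for chrom, lab in zip(self.chroms, labels):
            groups.setdefault(int(lab), set()).add(chrom)
        return frozenset(frozenset(g) for g in groups.values())


def chromosome_cluster(m: ContactMatrix) -> ChromosomeClustering:
    """Average-linkage clustering of the collapsed inter-chromosome map.

    The collapsed value for a chromosome pair is the mean trans signal over
    unmasked bin pairs (a mean, not a sum, so chromosome length does not
    dominate).  Rows are correlated pairwise-complete (the undefined
    diagonal is dropped) and clustered on 1 - correlation.
    """
    chroms = m.bins.genome.names
    k = len(chroms)
    if k < 3:
        raise ValueError("chromosome clustering requires >= 3 chromosomes")
    collapsed = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(a + 1, k):
            block = m.trans_block(chroms[a], chroms[b])
            alo, ahi = m.bins.chrom_range(chroms[a])
            blo, bhi = m.bins.chrom_range(chroms[b])
            valid = np.outer(~m.mask[alo:ahi], ~m.mask[blo:bhi])
            if valid.any():
                collapsed[a, b] = collapsed[b, a] = block[valid].mean()

    corr = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            cols = [c for c in range(k) if c not in (a, b)]
            ra, rb = collapsed[a, cols], collapsed[b, cols]
            ok = np.isfinite(ra) & np.isfinite(rb)
            if ok.sum() >= 2 and ra[ok].std() > 0 and rb[ok].std() > 0:
                corr[a, b] = corr[b, a] = float(np.corrcoef(ra[ok], rb[ok])[0, 1])
            else:
                corr[a, b] = corr[b, a] = 0.0

    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = sch.average(squareform(dist, checks=False))
    order = tuple(chroms[i] for i in sch.leaves_list(linkage))
    return ChromosomeClustering(tuple(chroms), collapsed, corr, linkage, order)
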