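"""Seeded generator of paired normal/tumor Hi-C datasets with known truth.

The generator emulates the statistical structures a comparative Hi-C
analysis rests on, on a desk-scale genome (three chromosomes, ~100 Mb):

* power-law distance decay of cis contacts, mu ~ A * d^alpha (d in bins;
  the diagonal uses the d=1 value);
* A/B compartment plaid: same-label bin pairs boosted by a factor k;
* TAD blocks: same-domain pairs boosted by an enrichment factor;
* chromatin loops: 3x3-bin Gaussian dots (sigma = 1 bin) at anchor pairs;
* per-bin multiplicative bias, log-uniform, so balancing has real work;
* flat trans background plus planted translocation blocks at a fold
  enrichment over background;
* Poisson count noise scaled to a target sequencing depth.

The tumor differs from the normal only by configured alterations: switched
compartment blocks, removed/added/moved TAD boundaries, removed/added
loops, and planted translocations.  A matched expression table ties gene
log2 fold changes to those alterations.  Every planted structure is
recorded in a machine-readable :class:`SyntheticTruth`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.stats import false_discovery_control, norm

from .contact_io import (
    BinTable,
    Breakpoint,
    ContactMatrix,
    GeneRecord,
    GenomeSpec,
    Loop,
    SvInterval,
    bin_genome,
    classify_de,
    write_bedpe_loops,
    write_gene_table,
    write_matrix,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTranslocation",
    "SyntheticTruth",
    "SyntheticDataset",
    "default_genome",
    "generate_pair",
    "generate_expression",
    "emit_files",
]

CONDITIONS = ("normal", "tumor")


def default_genome() -> GenomeSpec:
    """Three chromosomes totalling 100 Mb (200 bins at 500 kb)."""
    return GenomeSpec(("chr1", "chr2", "chr3"), (40_000_000, 35_000_000, 25_000_000))


@dataclass(frozen=True)
class SyntheticTranslocation:
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    fold: float = 8.0


@dataclass
class SyntheticConfig:
    """Study conditions for one paired dataset.

    Defaults emulate the comparison the pipeline is built for: decay
    exponent -1.2, plaid strength 1.5, within-TAD enrichment 3, ~600 kb
    median TAD size, loop dots at fold 4, biases log-uniform in [0.5, 2],
    activated (B2A) switches covering about twice the length of
    deactivated (A2B) ones, and one planted 1.2 Mb x 0.8 Mb translocation
    at 8x the trans background.
    """

    genome: GenomeSpec = field(default_factory=default_genome)
    compartment_res: int = 500_000
    tad_res: int = 50_000
    loop_res: int = 10_000
    trans_res: int = 40_000
    alpha: float = -1.2
    amplitude: float = 1.0
    plaid_strength: float = 1.5
    b2a_fraction: float = 0.166
    a2b_fraction: float = 0.084
    tad_spacing_bp: int = 600_000
    tad_enrichment: float = 3.0
    n_boundary_remove: int = 3
    n_boundary_add: int = 3
    n_boundary_move: int = 2
    tad_boundaries: dict[str, list[int]] | None = None  # explicit normal layout (bp)
    loops_per_chrom: int = 25
    n_loop_remove: int = 8
    n_loop_add: int = 8
    loop_fold: float = 4.0
    loop_sigma_bins: float = 1.0
    bias_range: tuple[float, float] = (0.5, 2.0)
    depth: float = 3.5e6
    trans_level: float = 0.002
    translocations: tuple[SyntheticTranslocation, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha >= 0:
            raise ValueError("decay exponent alpha must be negative")
        if self.plaid_strength <= 0:
            raise ValueError("plaid strength must be positive")
        if self.tad_enrichment < 1:
            raise ValueError("TAD enrichment must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.translocations is None:
            c = self.genome.names
            if len(c) >= 3:
                tr = SyntheticTranslocation(
                    c[1], 10_000_000, 10_000_000 + 30 * self.trans_res,
                    c[2], 8_000_000, 8_000_000 + 20 * self.trans_res, 8.0,
                )
                self.translocations = (tr,)
            else:
                self.translocations = ()
        for tr in self.translocations:
            if tr.end_a > self.genome.length_of(tr.chrom_a) or tr.end_b > self.genome.length_of(tr.chrom_b):
                raise ValueError("translocation span exceeds chromosome length")


# ---------------------------------------------------------------------------
# Truth record


@dataclass
class SyntheticTruth:
    """Machine-readable record of everything the generator planted."""

    config_seed: int
    # per compartment-res bin
    labels: dict[str, list[str]]          # condition -> A/B label per bin
    switch_classes: list[str]             # A2A/B2B/A2B/B2A per bin
    # boundary positions in bp, per condition, per chromosome
    boundaries: dict[str, dict[str, list[int]]]
    loops: dict[str, list[list]]          # condition -> [[chrom, s1, e1, s2, e2], ...]
    translocations: list[dict]
    bias: dict[str, dict[str, list[float]]]  # condition -> str(resolution) -> per-bin bias
    gene_classes: dict[str, dict] = field(default_factory=dict)  # gene_id -> {class, shift}

    def boundary_bins(self, condition: str, bins: BinTable) -> list[int]:
        out = []
        for chrom, positions in self.boundaries[condition].items():
            for pos in positions:
                out.append(bins.position_to_bin(chrom, min(pos, bins.genome.length_of(chrom) - 1)))
        return sorted(out)

    def specific_boundaries(self) -> dict[str, dict[str, list[int]]]:
        """Per condition, boundary positions absent from the other condition."""
        out: dict[str, dict[str, list[int]]] = {}
        for cond, other in (("normal", "tumor"), ("tumor", "normal")):
            out[cond] = {}
            for chrom in self.boundaries[cond]:
                other_set = set(self.boundaries[other].get(chrom, ()))
                out[cond][chrom] = [p for p in self.boundaries[cond][chrom] if p not in other_set]
        return out

    def loops_of(self, condition: str) -> list[Loop]:
        return [Loop.make(c, s1, e1, s2, e2) for c, s1, e1, s2, e2 in self.loops[condition]]

    def specific_loops_of(self, condition: str) -> list[Loop]:
        other = "tumor" if condition == "normal" else "normal"
        other_set = {tuple(x) for x in self.loops[other]}
        return [
            Loop.make(*x) for x in self.loops[condition] if tuple(x) not in other_set
        ]

    def activity_track(self, bins: BinTable, condition: str = "normal") -> np.ndarray:
        """Reference activity per bin of ``bins``: 1 in A-label regions, 0 in B."""
        comp_labels = self.labels[condition]
        genome = bins.genome
        comp_bins = bin_genome(genome, self._comp_res(bins))
        track = np.zeros(bins.n_bins)
        for i in range(bins.n_bins):
            chrom = bins.chrom_of(i)
            mid = int((bins.starts[i] + bins.ends[i]) // 2)
            j = comp_bins.position_to_bin(chrom, mid)
            track[i] = 1.0 if comp_labels[j] == "A" else 0.0
        return track

    def _comp_res(self, bins: BinTable) -> int:
        # the label list length identifies the compartment binning
        n = len(self.labels["normal"])
        for res in (500_000, 250_000, 100_000, 1_000_000):
            if bin_genome(bins.genome, res).n_bins == n:
                return res
        raise ValueError("cannot infer compartment resolution from truth")

    def to_dict(self) -> dict:
        return {
            "config_seed": self.config_seed,
            "labels": self.labels,
            "switch_classes": self.switch_classes,
            "boundaries": self.boundaries,
            "loops": self.loops,
            "translocations": self.translocations,
            "bias": self.bias,
            "gene_classes": self.gene_classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            d["config_seed"],
            d["labels"],
            d["switch_classes"],
            d["boundaries"],
            d["loops"],
            d["translocations"],
            d["bias"],
            d.get("gene_classes", {}),
        )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: SyntheticTruth
    matrices: dict[tuple[str, int], ContactMatrix]  # (condition, resolution) -> matrix
    genes: list[GeneRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Layout generation


def _compartment_layout(cfg: SyntheticConfig, rng: np.random.Generator):
    """Per-chrom alternating A/B blocks; tumor flips some blocks each way."""
    genome = cfg.genome
    comp_bins = bin_genome(genome, cfg.compartment_res)
    normal = np.empty(comp_bins.n_bins, dtype=object)
    blocks: list[tuple[int, int, str]] = []  # (lo, hi, label) global comp-bin idx
    for chrom in genome.names:
        lo, hi = comp_bins.chrom_range(chrom)
        label = rng.choice(["A", "B"])
        pos = lo
        while pos < hi:
            size = int(rng.integers(4, 13))
            end = min(pos + size, hi)
            normal[pos:end] = label
            blocks.append((pos, end, label))
            label = "A" if label == "B" else "B"
            pos = end

    tumor = normal.copy()
    n_bins = comp_bins.n_bins

    def flip(source_label: str, target_fraction: float) -> None:
        budget = int(round(target_fraction * n_bins))
        candidates = [b for b in blocks if b[2] == source_label]
        order = rng.permutation(len(candidates))
        flipped = 0
        for k in order:
            lo, hi, _ = candidates[k]
            if flipped >= budget:
                break
            tumor[lo:hi] = "A" if source_label == "B" else "B"
            flipped += hi - lo

    flip("B", cfg.b2a_fraction)
    flip("A", cfg.a2b_fraction)

    switch = []
    for a, b in zip(normal, tumor):
        if a == b:
            switch.append("A2A" if a == "A" else "B2B")
        else:
            switch.append("A2B" if a == "A" else "B2A")
    return comp_bins, normal, tumor, switch


def _label_change_edges(comp_bins: BinTable, labels, chrom: str) -> set[int]:
    lo, hi = comp_bins.chrom_range(chrom)
    return {
        int(comp_bins.starts[i])
        for i in range(lo + 1, hi)
        if labels[i] != labels[i - 1]
    }


def _tad_layout(cfg: SyntheticConfig, comp_bins: BinTable, labels: dict, rng: np.random.Generator):
    """Boundary bp positions per chromosome per condition.

    A shared set of boundaries is sampled with ~``tad_spacing_bp`` median
    gaps; compartment label-change edges of each condition are boundaries
    too (plaid transitions coincide with domain borders), so a flipped
    block that merges with its neighbor loses that edge in the tumor.
    """
    res = cfg.tad_res
    min_gap = 2 * res
    # label-change edges only matter when the plaid is actually on
    if cfg.plaid_strength != 1.0:
        edges = {
            cond: {c: _label_change_edges(comp_bins, labels[cond], c) for c in cfg.genome.names}
            for cond in CONDITIONS
        }
    else:
        edges = {cond: {c: set() for c in cfg.genome.names} for cond in CONDITIONS}
    normal: dict[str, list[int]] = {}
    tumor: dict[str, list[int]] = {}
    for chrom in cfg.genome.names:
        length = cfg.genome.length_of(chrom)
        all_edges = edges["normal"][chrom] | edges["tumor"][chrom]
        positions: set[int] = set()
        if cfg.tad_boundaries is not None:
            positions = {int(p) for p in cfg.tad_boundaries.get(chrom, ())}
            for p, q in zip(sorted(positions), sorted(positions)[1:]):
                if q - p < min_gap:
                    raise ValueError(
                        f"planted TAD boundaries {p} and {q} on {chrom} closer than 2 bins"
                    )
        else:
            pos = 0
            while True:
                gap = int(np.exp(rng.normal(np.log(cfg.tad_spacing_bp), 0.35)))
                gap = max(min_gap, round(gap / res) * res)
                pos += gap
                if pos >= length - min_gap:
                    break
                if all(abs(pos - e) >= min_gap for e in all_edges):
                    positions.add(pos)
        normal[chrom] = sorted(positions | edges["normal"][chrom])
        tumor[chrom] = sorted(positions | edges["tumor"][chrom])

    # tumor alterations: remove / add / move, never touching compartment edges
    comp_edge_set = {
        c: edges["normal"][c] | edges["tumor"][c] for c in cfg.genome.names
    }
    removable = [
        (c, p) for c in tumor for p in tumor[c] if p not in comp_edge_set[c]
    ]
    rng.shuffle(removable)
    for c, p in removable[: cfg.n_boundary_remove]:
        tumor[c].remove(p)
    removable = removable[cfg.n_boundary_remove:]

    moved = 0
    for c, p in removable:
        if moved >= cfg.n_boundary_move:
            break
        shift = int(rng.choice([-4, -3, 3, 4])) * res
        newp = p + shift
        near = [q for q in tumor[c] if q != p] + sorted(comp_edge_set[c])
        if 2 * res <= newp <= cfg.genome.length_of(c) - 2 * res and all(
            abs(newp - q) >= 2 * res for q in near
        ):
            tumor[c].remove(p)
            tumor[c].append(newp)
            moved += 1

    added = 0
    attempts = 0
    chroms = list(cfg.genome.names)
    while added < cfg.n_boundary_add and attempts < 1000:
        attempts += 1
        c = chroms[int(rng.integers(len(chroms)))]
        newp = int(rng.integers(4, cfg.genome.length_of(c) // cfg.tad_res - 4)) * cfg.tad_res
        if all(abs(newp - q) >= 2 * cfg.tad_res for q in tumor[c] + normal[c]):
            tumor[c].append(newp)
            added += 1
    for c in tumor:
        tumor[c] = sorted(tumor[c])
    return normal, tumor


def _loop_layout(cfg: SyntheticConfig, rng: np.random.Generator):
    res = cfg.loop_res
    normal: list[Loop] = []
    for chrom in cfg.genome.names:
        length = cfg.genome.length_of(chrom)
        for _ in range(cfg.loops_per_chrom):
            span = int(rng.integers(20, 121)) * res  # 200 kb .. 1.2 Mb
            a1 = int(rng.integers(0, (length - span - res) // res)) * res
            normal.append(Loop.make(chrom, a1, a1 + res, a1 + span, a1 + span + res))
    normal = sorted(set(normal))
    order = rng.permutation(len(normal))
    removed = {normal[i] for i in order[: cfg.n_loop_remove]}
    tumor = [lp for lp in normal if lp not in removed]
    for _ in range(cfg.n_loop_add):
        chrom = cfg.genome.names[int(rng.integers(len(cfg.genome.names)))]
        length = cfg.genome.length_of(chrom)
        span = int(rng.integers(20, 121)) * res
        a1 = int(rng.integers(0, (length - span - res) // res)) * res
        tumor.append(Loop.make(chrom, a1, a1 + res, a1 + span, a1 + span + res))
    return normal, sorted(set(tumor))


# ---------------------------------------------------------------------------
# Expected matrices and sampling


def _label_per_bin(bins: BinTable, comp_bins: BinTable, labels) -> np.ndarray:
    out = np.empty(bins.n_bins, dtype=object)
    for i in range(bins.n_bins):
        chrom = bins.chrom_of(i)
        mid = int((bins.starts[i] + bins.ends[i]) // 2)
        out[i] = labels[comp_bins.position_to_bin(chrom, mid)]
    return out


def _expected_matrix(
    cfg: SyntheticConfig,
    condition: str,
    resolution: int,
    comp_bins: BinTable,
    labels,
    boundaries: dict[str, list[int]],
    loops: list[Loop],
    bias: np.ndarray,
) -> tuple[BinTable, np.ndarray]:
    bins = bin_genome(cfg.genome, resolution)
    n = bins.n_bins
    mu = np.zeros((n, n))
    lab = _label_per_bin(bins, comp_bins, labels)

    for chrom in cfg.genome.names:
        lo, hi = bins.chrom_range(chrom)
        nc = hi - lo
        idx = np.arange(nc)
        d = np.abs(idx[:, None] - idx[None, :])
        base = cfg.amplitude * np.maximum(d, 1).astype(float) ** cfg.alpha
        l = lab[lo:hi]
        plaid = np.where(l[:, None] == l[None, :], cfg.plaid_strength, 1.0)
        bpos = np.asarray(boundaries.get(chrom, ()), dtype=float)
        mids = (bins.starts[lo:hi] + bins.ends[lo:hi]) / 2
        tad_id = np.searchsorted(bpos, mids)
        tadf = np.where(tad_id[:, None] == tad_id[None, :], cfg.tad_enrichment, 1.0)
        block = base * plaid * tadf
        # loop dots: multiplicative Gaussian bumps at anchor bin pairs.
        # A loop is a focal 10 kb-scale enrichment; at bins much coarser
        # than the anchors it dilutes away, so dots are only stamped at
        # resolutions within 5x of the anchor width.
        sig2 = 2 * cfg.loop_sigma_bins**2
        dots = loops if resolution <= 5 * cfg.loop_res else []
        for lp in dots:
            if lp.chrom != chrom:
                continue
            ai = lp.start1 // resolution
            aj = lp.start2 // resolution
            if ai == aj:
                continue
            for di in range(-1, 2):
                for dj in range(-1, 2):
                    i, j = ai + di, aj + dj
                    if 0 <= i < nc and 0 <= j < nc and i != j:
                        f = 1 + (cfg.loop_fold - 1) * np.exp(-(di**2 + dj**2) / sig2)
                        block[i, j] *= f
                        block[j, i] *= f
        mu[lo:hi, lo:hi] = block

    # trans background and planted translocation blocks
    chroms = cfg.genome.names
    for a in range(len(chroms)):
        for b in range(a + 1, len(chroms)):
            alo, ahi = bins.chrom_range(chroms[a])
            blo, bhi = bins.chrom_range(chroms[b])
            # per-entry trans level scales with resolution so the trans
            # fraction of the library is resolution-independent
            level = cfg.trans_level * cfg.amplitude * (resolution / cfg.tad_res)
            rect = np.full((ahi - alo, bhi - blo), level)
            if condition == "tumor":
                for tr in cfg.translocations:
                    pair = {tr.chrom_a: (tr.start_a, tr.end_a), tr.chrom_b: (tr.start_b, tr.end_b)}
                    if chroms[a] in pair and chroms[b] in pair:
                        sa, ea = pair[chroms[a]]
                        sb, eb = pair[chroms[b]]
                        rect[sa // resolution : (ea - 1) // resolution + 1,
                             sb // resolution : (eb - 1) // resolution + 1] *= tr.fold
            mu[alo:ahi, blo:bhi] = rect
            mu[blo:bhi, alo:ahi] = rect.T

    mu *= np.outer(bias, bias)
    upper_total = np.triu(mu).sum()
    mu *= cfg.depth / upper_total
    return bins, mu


def _draw_bias(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.bias_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def generate_pair(cfg: SyntheticConfig, noiseless: bool = False) -> SyntheticDataset:
    """Generate the paired dataset at all configured resolutions.

    With ``noiseless=True`` the expected values themselves are emitted
    (no Poisson sampling, biases forced to 1) — useful as exact inputs.
    """
    layout_rng = np.random.default_rng([cfg.seed, 101])
    comp_bins, lab_n, lab_t, switch = _compartment_layout(cfg, layout_rng)
    bnd_n, bnd_t = _tad_layout(
        cfg, comp_bins, {"normal": lab_n, "tumor": lab_t}, layout_rng
    )
    loops_n, loops_t = _loop_layout(cfg, layout_rng)

    labels = {"normal": lab_n, "tumor": lab_t}
    boundaries = {"normal": bnd_n, "tumor": bnd_t}
    loops = {"normal": loops_n, "tumor": loops_t}

    resolutions = sorted({cfg.compartment_res, cfg.tad_res, cfg.trans_res})
    matrices: dict[tuple[str, int], ContactMatrix] = {}
    bias_record: dict[str, dict[str, list[float]]] = {c: {} for c in CONDITIONS}
    for ci, cond in enumerate(CONDITIONS):
        for res in resolutions:
            bins = bin_genome(cfg.genome, res)
            if noiseless:
                bias = np.ones(bins.n_bins)
            else:
                bias_rng = np.random.default_rng([cfg.seed, 211, ci, res])
                bias = _draw_bias(cfg, bins.n_bins, bias_rng)
            bias_record[cond][str(res)] = [float(x) for x in bias]
            _, mu = _expected_matrix(
                cfg, cond, res, comp_bins, labels[cond], boundaries[cond], loops[cond], bias
            )
            upper = np.triu(mu)
            if noiseless:
                counts = upper
            else:
                count_rng = np.random.default_rng([cfg.seed, 307, ci, res])
                counts = count_rng.poisson(upper).astype(float)
            matrices[(cond, res)] = ContactMatrix(bins, sp.csr_matrix(counts), "raw")

    truth = SyntheticTruth(
        cfg.seed,
        {c: [str(x) for x in labels[c]] for c in CONDITIONS},
        list(switch),
        {c: {k: list(map(int, v)) for k, v in boundaries[c].items()} for c in CONDITIONS},
        {
            c: [[lp.chrom, lp.start1, lp.end1, lp.start2, lp.end2] for lp in loops[c]]
            for c in CONDITIONS
        },
        [
            {
                "chrom_a": tr.chrom_a, "start_a": tr.start_a, "end_a": tr.end_a,
                "chrom_b": tr.chrom_b, "start_b": tr.start_b, "end_b": tr.end_b,
                "fold": tr.fold,
            }
            for tr in cfg.translocations
        ],
        bias_record,
    )
    return SyntheticDataset(cfg, truth, matrices)


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionEffects:
    """Per-class log2FC shifts (classes with sign=None draw a random sign)."""

    b2a: float = 1.5
    a2b: float = -1.5
    tad_altered: float = 1.5     # magnitude, random sign
    loop_anchor: float = 1.5     # magnitude, random sign
    sigma: float = 0.5
    se: float = 0.35             # measurement scale for p-values
    genes_per_class: int = 200
    gene_length: int = 10_000
    min_spacing: int = 2_000


def _altered_tad_intervals(truth: SyntheticTruth, genome: GenomeSpec) -> list[tuple[str, int, int]]:
    """bp intervals of TADs touched by condition-specific boundaries."""
    specific = truth.specific_boundaries()
    out = []
    for cond in CONDITIONS:
        for chrom, positions in truth.boundaries[cond].items():
            spec_here = set(specific["normal"].get(chrom, ())) | set(
                specific["tumor"].get(chrom, ())
            )
            for a, b in zip(positions, positions[1:]):
                if any(a <= s <= b for s in spec_here):
                    out.append((chrom, a, b))
    return out


def generate_expression(
    truth: SyntheticTruth,
    genome: GenomeSpec,
    effects: ExpressionEffects | None = None,
    seed: int = 0,
    compartment_res: int = 500_000,
) -> list[GeneRecord]:
    """Place genes in each structural class and draw matched DE statistics.

    Gene log2 fold changes are Normal(shift, sigma) with the class shift;
    p-values come from a two-sided normal test of log2FC at scale ``se``
    and are BH-adjusted across all genes.  Gene placements respect a
    minimum spacing; exceeding the capacity of a class region is an error.
    """
    effects = effects or ExpressionEffects()
    rng = np.random.default_rng([seed, 401])
    comp_bins = bin_genome(genome, compartment_res)

    regions: dict[str, list[tuple[str, int, int]]] = {}
    switch = np.asarray(truth.switch_classes, dtype=object)
    for cls, wanted in (("b2a", ("B2A",)), ("a2b", ("A2B",)), ("stable", ("A2A", "B2B"))):
        sel = np.flatnonzero(np.isin(switch, wanted))
        regions[cls] = [
            (comp_bins.chrom_of(i), int(comp_bins.starts[i]), int(comp_bins.ends[i]))
            for i in sel
        ]
    regions["tad_altered"] = _altered_tad_intervals(truth, genome)
    anchors = []
    for cond in CONDITIONS:
        for lp in truth.specific_loops_of(cond):
            anchors.append((lp.chrom, lp.start1, lp.end1))
            anchors.append((lp.chrom, lp.start2, lp.end2))
    regions["loop_anchor"] = anchors

    shifts = {
        "b2a": (effects.b2a, False),
        "a2b": (effects.a2b, False),
        "stable": (0.0, False),
        "tad_altered": (effects.tad_altered, True),
        "loop_anchor": (effects.loop_anchor, True),
    }

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    genes_raw: list[tuple[str, str, int, int, str, float]] = []
    def collides(chrom: str, start: int, end: int) -> bool:
        return any(
            start < e + effects.min_spacing and s - effects.min_spacing < end
            for s, e in placed[chrom]
        )

    for cls, intervals in regions.items():
        intervals = sorted(set(intervals))
        if not intervals:
            continue
        shift_mag, random_sign = shifts[cls]
        # cap by region capacity at the configured footprint so narrow
        # feature classes (e.g. loop anchors) get as many genes as fit
        capacity = int(
            sum(hi - lo for _, lo, hi in intervals) / (effects.gene_length + effects.min_spacing)
        )
        target = min(effects.genes_per_class, max(capacity, 1))

        def footprint(lo: int, hi: int) -> int:
            return effects.gene_length if hi - lo > effects.gene_length else max(hi - lo - 1, 1000)

        count = 0
        attempts = 0
        max_attempts = target * 200
        while count < target and attempts < max_attempts:
            attempts += 1
            chrom, lo, hi = intervals[int(rng.integers(len(intervals)))]
            glen = footprint(lo, hi)
            start = lo if hi - lo <= glen else int(rng.integers(lo, hi - glen))
            end = min(start + glen, genome.length_of(chrom))
            if collides(chrom, start, end):
                continue
            placed[chrom].append((start, end))
            shift = shift_mag * (rng.choice([-1.0, 1.0]) if random_sign else 1.0)
            genes_raw.append((f"G_{cls}_{count:04d}", chrom, start, end, cls, shift))
            count += 1
        # deterministic left-to-right fill for nearly saturated regions
        for chrom, lo, hi in intervals:
            if count >= target:
                break
            pos = lo
            while count < target:
                glen = footprint(lo, hi)
                if pos + glen > hi:
                    break
                end = min(pos + glen, genome.length_of(chrom))
                if collides(chrom, pos, end):
                    pos += effects.min_spacing
                    continue
                placed[chrom].append((pos, end))
                shift = shift_mag * (rng.choice([-1.0, 1.0]) if random_sign else 1.0)
                genes_raw.append((f"G_{cls}_{count:04d}", chrom, pos, end, cls, shift))
                count += 1
                pos = end + effects.min_spacing
        if count < target and effects.genes_per_class > capacity:
            pass  # capacity cap already applied; partial fill acceptable
        if count == 0:
            raise ValueError(
                f"cannot place genes of class {cls!r} at the configured spacing"
            )
        if count < min(effects.genes_per_class, capacity) and capacity < effects.genes_per_class:
            continue
        if count < target:
            raise ValueError(
                f"cannot place {target} genes of class {cls!r} at the configured spacing"
            )

    strands = rng.choice(["+", "-"], size=len(genes_raw))
    lfc = np.array([s for *_, s in genes_raw]) + rng.normal(0, effects.sigma, len(genes_raw))
    base_mean = np.exp(rng.normal(5, 1, len(genes_raw)))
    pvals = 2 * norm.sf(np.abs(lfc) / effects.se)
    padj = false_discovery_control(pvals, method="bh")

    genes = []
    for k, (gid, chrom, start, end, cls, shift) in enumerate(genes_raw):
        genes.append(
            GeneRecord(
                gid, chrom, start, end, str(strands[k]),
                float(base_mean[k]), float(lfc[k]), float(padj[k]),
                classify_de(float(lfc[k]), float(padj[k])),
            )
        )
        truth.gene_classes[gid] = {"class": cls, "shift": float(shift)}
    return genes


# ---------------------------------------------------------------------------
# SVs / breakpoints / file emission


def planted_breakpoints(truth: SyntheticTruth) -> list[Breakpoint]:
    """One WGS-style breakpoint at the start corner of each planted event."""
    return [
        Breakpoint(t["chrom_a"], t["start_a"], t["chrom_b"], t["start_b"])
        for t in truth.translocations
    ]


def synthetic_svs(
    truth: SyntheticTruth, genome: GenomeSpec, seed: int, n_per_type: int = 5
) -> list[SvInterval]:
    """Tumor SV intervals: planted translocation spans plus seeded random SVs."""
    rng = np.random.default_rng([seed, 503])
    svs: list[SvInterval] = []
    for t in truth.translocations:
        svs.append(SvInterval("translocation", t["chrom_a"], t["start_a"], t["end_a"]))
        svs.append(SvInterval("translocation", t["chrom_b"], t["start_b"], t["end_b"]))
    for sv_type in ("deletion", "duplication", "inversion", "cnv_gain", "cnv_loss"):
        for _ in range(n_per_type):
            chrom = genome.names[int(rng.integers(len(genome.names)))]
            length = int(rng.integers(100_000, 1_000_000))
            start = int(rng.integers(0, genome.length_of(chrom) - length))
            svs.append(SvInterval(sv_type, chrom, start, start + length))
    return svs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def emit_files(dataset: SyntheticDataset, directory) -> dict:
    """Write every output format and a manifest with checksums and the seed."""
    outdir = Path(directory)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    for (cond, res), m in sorted(dataset.matrices.items()):
        stem = f"{cond}_{res}"
        write_matrix(m, outdir / f"{stem}.matrix", outdir / f"{stem}_abs.bed")
        paths[f"matrix_{stem}"] = f"{stem}.matrix"
        paths[f"bins_{stem}"] = f"{stem}_abs.bed"

    for cond in CONDITIONS:
        p = outdir / f"{cond}_loops.bedpe"
        write_bedpe_loops(dataset.truth.loops_of(cond), p)
        paths[f"loops_{cond}"] = p.name

    svs = synthetic_svs(dataset.truth, dataset.config.genome, dataset.config.seed)
    with open(outdir / "tumor_sv.bed", "w") as fh:
        for sv in svs:
            fh.write(f"{sv.chrom}\t{sv.start}\t{sv.end}\t{sv.sv_type}\n")
    paths["sv"] = "tumor_sv.bed"

    with open(outdir / "breakpoints.tsv", "w") as fh:
        fh.write("chromA\tposA\tchromB\tposB\n")
        for bp in planted_breakpoints(dataset.truth):
            fh.write(f"{bp.chrom_a}\t{bp.pos_a}\t{bp.chrom_b}\t{bp.pos_b}\n")
    paths["breakpoints"] = "breakpoints.tsv"

    if dataset.genes:
        write_gene_table(dataset.genes, outdir / "genes.tsv")
        paths["genes"] = "genes.tsv"

    with open(outdir / "truth.json", "w") as fh:
        json.dump(dataset.truth.to_dict(), fh, indent=1, sort_keys=True)
    paths["truth"] = "truth.json"

    genome = dataset.config.genome
    manifest = {
        "seed": dataset.config.seed,
        "genome": {c: int(l) for c, l in zip(genome.names, genome.lengths)},
        "paths": paths,
        "sha256": {k: _sha256(outdir / v) for k, v in paths.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
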