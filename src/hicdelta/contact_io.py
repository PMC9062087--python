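"""Genomic data model and file I/O.

Containers for binned genomes and sparse symmetric contact matrices, plus
readers/writers for the text formats the pipeline consumes and emits:

* HiC-Pro style sparse matrices: a BED-like bin file (chrom, start, end,
  1-based bin id) and a triplet matrix file (id_a, id_b, value);
* BEDPE loop lists;
* BED structural-variant intervals (type in column 4);
* TSV gene tables with differential-expression results;
* TSV translocation breakpoint tables.

Coordinates are 0-based half-open everywhere in memory; the 1-based HiC-Pro
bin ids are converted at the file boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GenomeSpec",
    "BinTable",
    "ContactMatrix",
    "Loop",
    "GeneRecord",
    "SvInterval",
    "Breakpoint",
    "LoopReadResult",
    "FileFormatError",
    "bin_genome",
    "read_matrix",
    "write_matrix",
    "read_bedpe_loops",
    "write_bedpe_loops",
    "read_gene_table",
    "write_gene_table",
    "read_sv_table",
    "read_breakpoints",
    "classify_de",
    "SV_TYPES",
]


class FileFormatError(ValueError):
    """A malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# Genome / bins


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome names and their lengths in bp."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeSpec":
        return cls(tuple(d.keys()), tuple(int(v) for v in d.values()))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names


@dataclass(frozen=True)
class BinTable:
    """A fixed-resolution tiling of a genome into bins.

    Bins tile each chromosome without gaps or overlap; every bin has width
    ``resolution`` except possibly the last per chromosome.  Global indices
    are dense ``0..n_bins-1`` in genome order.
    """

    genome: GenomeSpec
    resolution: int
    chrom_ids: np.ndarray = field(repr=False)   # per-bin index into genome.names
    starts: np.ndarray = field(repr=False)      # bp, 0-based
    ends: np.ndarray = field(repr=False)        # bp, half-open

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Global [lo, hi) index range of the bins of one chromosome."""
        cid = self.genome.names.index(chrom)
        idx = np.flatnonzero(self.chrom_ids == cid)
        return int(idx[0]), int(idx[-1]) + 1

    def chrom_of(self, bin_index: int) -> str:
        return self.genome.names[int(self.chrom_ids[bin_index])]

    def position_to_bin(self, chrom: str, pos: int) -> int:
        """Global bin index containing bp position ``pos`` (0-based)."""
        length = self.genome.length_of(chrom)
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom} (length {length})")
        lo, hi = self.chrom_range(chrom)
        local = min(pos // self.resolution, hi - lo - 1)
        return lo + int(local)

    def to_frame(self) -> pd.DataFrame:
        names = np.asarray(self.genome.names, dtype=object)
        return pd.DataFrame(
            {
                "chrom": names[self.chrom_ids],
                "start": self.starts,
                "end": self.ends,
                "index": np.arange(self.n_bins),
            }
        )

    def same_binning(self, other: "BinTable") -> bool:
        return (
            self.genome == other.genome
            and self.resolution == other.resolution
            and self.n_bins == other.n_bins
        )


def bin_genome(genome: GenomeSpec, resolution: int) -> BinTable:
    """Tile ``genome`` into bins of ``resolution`` bp (last bin may be short)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    chrom_ids, starts, ends = [], [], []
    for cid, length in enumerate(genome.lengths):
        n = math.ceil(length / resolution)
        for k in range(n):
            chrom_ids.append(cid)
            starts.append(k * resolution)
            ends.append(min((k + 1) * resolution, length))
    return BinTable(
        genome,
        int(resolution),
        np.asarray(chrom_ids, dtype=np.int32),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Contact matrix


@dataclass
class ContactMatrix:
    """Symmetric sparse contact matrix over a :class:`BinTable`.

    Only the upper triangle (i <= j) is stored; lookups symmetrize.  ``mask``
    marks bins excluded from analysis (e.g. zero coverage after balancing).
    """

    bins: BinTable
    data: sp.csr_matrix = field(repr=False)     # upper triangle incl. diagonal
    kind: str = "raw"                           # "raw" | "normalized"
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = self.bins.n_bins
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match bin table")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_coo(
        cls,
        bins: BinTable,
        i: np.ndarray,
        j: np.ndarray,
        values: np.ndarray,
        kind: str = "raw",
        *,
        check_duplicates: bool = False,
    ) -> "ContactMatrix":
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        if check_duplicates:
            keys = lo * bins.n_bins + hi
            uniq, counts = np.unique(keys, return_counts=True)
            if np.any(counts > 1):
                dup = uniq[counts > 1][0]
                di, dj = divmod(int(dup), bins.n_bins)
                raise FileFormatError(f"duplicate matrix entry for bins ({di}, {dj})")
        mat = sp.coo_matrix((values, (lo, hi)), shape=(bins.n_bins, bins.n_bins))
        mat.sum_duplicates()
        return cls(bins, mat.tocsr(), kind)

    @classmethod
    def from_dense(cls, bins: BinTable, dense: np.ndarray, kind: str = "raw") -> "ContactMatrix":
        upper = sp.csr_matrix(np.triu(dense))
        return cls(bins, upper, kind)

    # -- access ------------------------------------------------------------

    def get(self, i: int, j: int) -> float:
        a, b = min(i, j), max(i, j)
        return float(self.data[a, b])

    def dense(self) -> np.ndarray:
        """Full symmetric dense matrix (masked bins zeroed)."""
        u = self.data.toarray()
        full = u + u.T - np.diag(np.diag(u))
        if self.mask.any():
            full[self.mask, :] = 0.0
            full[:, self.mask] = 0.0
        return full

    def cis_block(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Dense symmetric intra-chromosomal block and its local bin mask."""
        lo, hi = self.bins.chrom_range(chrom)
        u = self.data[lo:hi, lo:hi].toarray()
        block = u + u.T - np.diag(np.diag(u))
        local_mask = self.mask[lo:hi].copy()
        block[local_mask, :] = 0.0
        block[:, local_mask] = 0.0
        return block, local_mask

    def trans_block(self, chrom_a: str, chrom_b: str) -> np.ndarray:
        """Dense rectangular inter-chromosomal block (rows=chrom_a)."""
        alo, ahi = self.bins.chrom_range(chrom_a)
        blo, bhi = self.bins.chrom_range(chrom_b)
        if alo < blo:
            block = self.data[alo:ahi, blo:bhi].toarray()
        else:
            block = self.data[blo:bhi, alo:ahi].toarray().T
        block = block.copy()
        block[self.mask[alo:ahi], :] = 0.0
        block[:, self.mask[blo:bhi]] = 0.0
        return block

    # -- aggregates --------------------------------------------------------

    def _pair_chrom_ids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        coo = self.data.tocoo()
        keep = ~(self.mask[coo.row] | self.mask[coo.col])
        return coo.row[keep], coo.col[keep], coo.data[keep]

    def cis_total(self) -> float:
        r, c, v = self._pair_chrom_ids()
        cids = self.bins.chrom_ids
        return float(v[cids[r] == cids[c]].sum())

    def trans_total(self) -> float:
        r, c, v = self._pair_chrom_ids()
        cids = self.bins.chrom_ids
        return float(v[cids[r] != cids[c]].sum())

    def total(self) -> float:
        _, _, v = self._pair_chrom_ids()
        return float(v.sum())

    def scaled(self, factor: float) -> "ContactMatrix":
        return replace(self, data=self.data.multiply(factor).tocsr(), mask=self.mask.copy())


# ---------------------------------------------------------------------------
# Record types


@dataclass(frozen=True, order=True)
class Loop:
    """An intra-chromosomal chromatin loop between two anchor intervals."""

    chrom: str
    start1: int
    end1: int
    start2: int
    end2: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start1 > self.start2:
            raise ValueError("anchors must be in genomic order; use Loop.make()")

    @classmethod
    def make(cls, chrom, start1, end1, start2, end2, score=None) -> "Loop":
        """Build a loop with anchors canonically ordered by start."""
        a = (int(start1), int(end1))
        b = (int(start2), int(end2))
        if a > b:
            a, b = b, a
        return cls(chrom, a[0], a[1], b[0], b[1], score)

    @property
    def length(self) -> float:
        """Anchor-midpoint separation in bp."""
        return (self.start2 + self.end2) / 2 - (self.start1 + self.end1) / 2


DE_STATUSES = ("up", "down", "not-DE")


def classify_de(log2fc: float, padj: float, *, padj_max: float = 0.05, lfc_min: float = 1.0) -> str:
    """DE status label under adjusted-p and |log2FC| thresholds."""
    if np.isfinite(padj) and padj < padj_max and abs(log2fc) >= lfc_min:
        return "up" if log2fc > 0 else "down"
    return "not-DE"


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    base_mean: float
    log2fc: float
    padj: float
    status: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.status not in DE_STATUSES:
            raise ValueError(f"gene {self.gene_id}: bad DE status {self.status!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


SV_TYPES = (
    "deletion",
    "duplication",
    "inversion",
    "translocation",
    "cnv_gain",
    "cnv_loss",
)

_SV_ALIASES = {
    "del": "deletion",
    "deletion": "deletion",
    "dup": "duplication",
    "duplication": "duplication",
    "inv": "inversion",
    "inversion": "inversion",
    "tra": "translocation",
    "bnd": "translocation",
    "translocation": "translocation",
    "gain": "cnv_gain",
    "cnv_gain": "cnv_gain",
    "cnv-gain": "cnv_gain",
    "loss": "cnv_loss",
    "cnv_loss": "cnv_loss",
    "cnv-loss": "cnv_loss",
}


@dataclass(frozen=True)
class SvInterval:
    sv_type: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.start >= self.end:
            raise ValueError("SV interval start must be < end")


@dataclass(frozen=True)
class Breakpoint:
    """A WGS-called translocation breakpoint joining two chromosomes."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int


# ---------------------------------------------------------------------------
# HiC-Pro sparse matrix I/O


def _read_bin_file(path) -> tuple[BinTable, dict[int, int]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FileFormatError(f"{path}:{lineno}: expected 4 columns in bin file")
            rows.append((parts[0], int(parts[1]), int(parts[2]), int(parts[3])))
    if not rows:
        raise FileFormatError(f"{path}: empty bin file")
    # chromosome order = order of first appearance
    names: list[str] = []
    for chrom, *_ in rows:
        if chrom not in names:
            names.append(chrom)
    lengths = {c: max(r[2] for r in rows if r[0] == c) for c in names}
    widths = [r[2] - r[1] for r in rows]
    resolution = max(widths)
    genome = GenomeSpec(tuple(names), tuple(lengths[c] for c in names))
    bins = bin_genome(genome, resolution)
    if bins.n_bins != len(rows):
        raise FileFormatError(f"{path}: bin file does not tile its genome at {resolution} bp")
    id_map = {r[3]: k for k, r in enumerate(rows)}
    return bins, id_map


def read_matrix(matrix_path, bin_path, kind: str = "raw") -> ContactMatrix:
    """Read a HiC-Pro sparse matrix (triplet file + BED-like bin file).

    Bin ids in the files are 1-based; duplicate (i, j) entries (after
    symmetrization) and negative values are rejected with their line number.
    """
    bins, id_map = _read_bin_file(bin_path)
    ii, jj, vv = [], [], []
    with open(matrix_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FileFormatError(f"{matrix_path}:{lineno}: expected 3 columns")
            try:
                a, b = int(parts[0]), int(parts[1])
                v = float(parts[2])
            except ValueError:
                raise FileFormatError(f"{matrix_path}:{lineno}: malformed line") from None
            if a not in id_map or b not in id_map:
                raise FileFormatError(f"{matrix_path}:{lineno}: unknown bin id")
            if v < 0:
                raise FileFormatError(f"{matrix_path}:{lineno}: negative value")
            ii.append(id_map[a])
            jj.append(id_map[b])
            vv.append(v)
    if not ii:
        empty = sp.csr_matrix((bins.n_bins, bins.n_bins))
        return ContactMatrix(bins, empty, kind)
    return ContactMatrix.from_coo(
        bins, np.array(ii), np.array(jj), np.array(vv), kind, check_duplicates=True
    )


def write_matrix(m: ContactMatrix, matrix_path, bin_path) -> None:
    """Write a matrix in the HiC-Pro dialect; round-trips with read_matrix."""
    frame = m.bins.to_frame()
    with open(bin_path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.index + 1}\n")
    coo = m.data.tocoo()
    order = np.lexsort((coo.col, coo.row))
    integral = m.kind == "raw" and np.allclose(coo.data, np.round(coo.data))
    with open(matrix_path, "w") as fh:
        for k in order:
            v = coo.data[k]
            if v == 0:
                continue
            sval = str(int(round(v))) if integral else repr(float(v))
            fh.write(f"{coo.row[k] + 1}\t{coo.col[k] + 1}\t{sval}\n")


# ---------------------------------------------------------------------------
# BEDPE loops


class LoopReadResult(NamedTuple):
    loops: list[Loop]
    n_rejected_inter: int


def read_bedpe_loops(path) -> LoopReadResult:
    """Read loops from BEDPE; inter-chromosomal rows are counted and dropped."""
    loops: list[Loop] = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "chrom1\t")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FileFormatError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
            c1, s1, e1, c2, s2, e2 = parts[:6]
            if c1 != c2:
                rejected += 1
                continue
            score = float(parts[6]) if len(parts) > 6 and parts[6] not in (".", "") else None
            loops.append(Loop.make(c1, int(s1), int(e1), int(s2), int(e2), score))
    return LoopReadResult(loops, rejected)


def write_bedpe_loops(loops: Iterable[Loop], path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            score = "." if lp.score is None else repr(lp.score)
            fh.write(
                f"{lp.chrom}\t{lp.start1}\t{lp.end1}\t{lp.chrom}\t{lp.start2}\t{lp.end2}\t{score}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables


def _validate_interval(genome: GenomeSpec, chrom: str, start: int, end: int, where: str) -> None:
    if chrom not in genome:
        raise FileFormatError(f"{where}: unknown chromosome {chrom!r}")
    if end > genome.length_of(chrom):
        raise FileFormatError(f"{where}: interval end {end} beyond {chrom} length")


def read_gene_table(
    path,
    genome: GenomeSpec | None = None,
    *,
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
) -> list[GeneRecord]:
    """Read a gene/DE TSV: gene_id, chrom, start, end, strand, baseMean, log2FC, padj.

    The DE status column is recomputed from the thresholds in effect.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "strand", "baseMean", "log2FC", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise FileFormatError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for k, row in enumerate(df.itertuples(index=False), 2):
        if genome is not None:
            _validate_interval(genome, row.chrom, int(row.start), int(row.end), f"{path}:{k}")
        padj = float(row.padj) if pd.notna(row.padj) else np.nan
        genes.append(
            GeneRecord(
                str(row.gene_id),
                str(row.chrom),
                int(row.start),
                int(row.end),
                str(row.strand),
                float(row.baseMean),
                float(row.log2FC),
                padj,
                classify_de(float(row.log2FC), padj, padj_max=padj_max, lfc_min=lfc_min),
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "baseMean": [g.base_mean for g in genes],
            "log2FC": [g.log2fc for g in genes],
            "padj": [g.padj for g in genes],
            "status": [g.status for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_sv_table(path, genome: GenomeSpec | None = None) -> list[SvInterval]:
    """Read SV intervals from BED-like TSV with the SV type in column 4."""
    svs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "chrom\t")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FileFormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, raw_type = parts[0], int(parts[1]), int(parts[2]), parts[3]
            key = raw_type.strip().lower()
            if key not in _SV_ALIASES:
                raise FileFormatError(f"{path}:{lineno}: unknown SV type {raw_type!r}")
            if genome is not None:
                _validate_interval(genome, chrom, start, end, f"{path}:{lineno}")
            svs.append(SvInterval(_SV_ALIASES[key], chrom, start, end))
    return svs


def read_breakpoints(path, genome: GenomeSpec | None = None) -> list[Breakpoint]:
    """Read breakpoints from TSV: chromA, posA, chromB, posB (header required)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chromA", "posA", "chromB", "posB"}
    if not required <= set(df.columns):
        raise FileFormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bps = []
    for k, row in enumerate(df.itertuples(index=False), 2):
        for chrom, pos in ((row.chromA, row.posA), (row.chromB, row.posB)):
            if genome is not None:
                if chrom not in genome:
                    raise FileFormatError(f"{path}:{k}: unknown chromosome {chrom!r}")
                if not 0 <= int(pos) < genome.length_of(chrom):
                    raise FileFormatError(f"{path}:{k}: position {pos} beyond {chrom}")
        bps.append(Breakpoint(str(row.chromA), int(row.posA), str(row.chromB), int(row.posB)))
    return bps
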