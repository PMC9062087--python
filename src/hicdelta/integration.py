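"""Joining gene expression to chromatin-structure alterations.

Genes are assigned (by midpoint bin) a compartment switch class, a TAD
stability status, and a loop-anchor status, then cross-tabulated against
their differential-expression call: up/down ratios per switch class, and
DEG/NDEG 2x2 tables per alteration axis, each with a Pearson chi-square
against the stable group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contact_io import GeneRecord
from .compartments import SwitchTrack
from .insulation_tads import TadSet
from .loops_compare import LoopComparison, anchor_intervals
from .stats import pearson_chi2

__all__ = [
    "GeneAnnotation",
    "ContingencyResult",
    "annotate_genes",
    "updown_by_class",
    "updown_from_counts",
    "deg_by_alteration",
    "build_report",
    "write_report",
]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    switch_class: str       # A2A | B2B | A2B | B2A | NA
    tad_status: str         # stable | altered | NA
    at_loop_anchor: bool
    de_status: str          # up | down | not-DE


@dataclass
class ContingencyResult:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    table: tuple[tuple[int, ...], ...]
    ratios: dict[str, float] = field(default_factory=dict)
    ratio_flags: dict[str, str] = field(default_factory=dict)
    chi2: float = 0.0
    dof: int = 1
    p_value: float = 1.0

    def to_dict(self) -> dict:
        return {
            "rows": list(self.row_labels),
            "cols": list(self.col_labels),
            "table": [list(r) for r in self.table],
            "ratios": {k: (None if not np.isfinite(v) else v) for k, v in self.ratios.items()},
            "ratio_flags": dict(self.ratio_flags),
            "chi2": self.chi2,
            "dof": self.dof,
            "p_value": self.p_value,
        }


def _ratio(num: int, den: int) -> tuple[float, str]:
    if den == 0 and num == 0:
        return float("nan"), "undefined"
    if den == 0:
        return float("inf"), "infinite"
    return num / den, "finite"


def annotate_genes(
    genes: Sequence[GeneRecord],
    switch_track: SwitchTrack | None = None,
    tad_sets: tuple[TadSet, TadSet] | None = None,
    loop_comparison: LoopComparison | None = None,
) -> list[GeneAnnotation]:
    """Annotate each gene by the structure tracks at its midpoint.

    Compartment class is the switch class of the bin containing the gene
    midpoint; TAD status is "altered" when the midpoint lies in an altered
    TAD of either condition; loop-anchor status is >= 1 bp overlap of the
    gene interval with any specific-loop anchor.  Missing tracks (or genes
    on chromosomes absent from them) yield NA.
    """
    specific_anchors: list[tuple[str, int, int]] = []
    if loop_comparison is not None:
        specific_anchors = anchor_intervals(loop_comparison.specific_a) + anchor_intervals(
            loop_comparison.specific_b
        )
    anchors_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in specific_anchors:
        anchors_by_chrom.setdefault(chrom, []).append((s, e))

    altered_by_chrom: dict[str, list[tuple[int, int]]] = {}
    tad_chroms: set[str] = set()
    if tad_sets is not None:
        for ts in tad_sets:
            res = ts.bins.resolution
            tad_chroms.update(ts.bins.genome.names)
            for t in ts.tads:
                if t.altered:
                    lo, _ = ts.bins.chrom_range(t.chrom)
                    start_bp = int(ts.bins.starts[t.start_bin])
                    end_bp = start_bp + t.size_bp(res)
                    altered_by_chrom.setdefault(t.chrom, []).append((start_bp, end_bp))

    out = []
    for g in genes:
        mid = g.midpoint
        if switch_track is not None and g.chrom in switch_track.bins.genome:
            switch = switch_track.class_of_position(g.chrom, mid)
        else:
            switch = "NA"
        if tad_sets is not None and g.chrom in tad_chroms:
            in_altered = any(s <= mid < e for s, e in altered_by_chrom.get(g.chrom, ()))
            tad_status = "altered" if in_altered else "stable"
        else:
            tad_status = "NA"
        at_anchor = any(g.start < e and s < g.end for s, e in anchors_by_chrom.get(g.chrom, ()))
        out.append(GeneAnnotation(g.gene_id, switch, tad_status, at_anchor, g.status))
    return out


# ---------------------------------------------------------------------------
# Up/down by compartment switch class


def updown_from_counts(counts: dict[str, tuple[int, int]]) -> dict[str, ContingencyResult]:
    """Up/down ratios per switch group and chi-square of each altered group vs stable.

    ``counts`` maps group name ("stable", "A2B", "B2A") to (n_up, n_down).
    Each altered group yields a 2x2 table [group, stable] x [up, down].
    The "stable" key holds the ratio alone (chi-square vs itself is 0).
    """
    if "stable" not in counts:
        raise ValueError("counts must include the 'stable' group")
    out: dict[str, ContingencyResult] = {}
    s_up, s_down = counts["stable"]
    for group, (up, down) in counts.items():
        ratio, flag = _ratio(up, down)
        if group == "stable":
            table = ((s_up, s_down),)
            res = ContingencyResult(
                ("stable",), ("up", "down"), table, {"up_down": ratio}, {"up_down": flag}
            )
        else:
            table = ((up, down), (s_up, s_down))
            stat, dof, p = pearson_chi2(table)
            res = ContingencyResult(
                (group, "stable"),
                ("up", "down"),
                table,
                {"up_down": ratio},
                {"up_down": flag},
                stat,
                dof,
                p,
            )
        out[group] = res
    return out


def updown_by_class(annotations: Sequence[GeneAnnotation]) -> dict[str, ContingencyResult]:
    """Count up/down genes in stable (A2A+B2B), A2B and B2A bins; test vs stable."""
    def count(group_classes: tuple[str, ...]) -> tuple[int, int]:
        up = sum(1 for a in annotations if a.switch_class in group_classes and a.de_status == "up")
        down = sum(
            1 for a in annotations if a.switch_class in group_classes and a.de_status == "down"
        )
        return up, down

    counts = {
        "stable": count(("A2A", "B2B")),
        "A2B": count(("A2B",)),
        "B2A": count(("B2A",)),
    }
    return updown_from_counts(counts)


# ---------------------------------------------------------------------------
# DEG/NDEG by alteration axis


AXES = ("compartment", "tad", "loop")


def deg_by_alteration(annotations: Sequence[GeneAnnotation], axis: str) -> ContingencyResult:
    """2x2 DEG/NDEG x altered/stable table for one alteration axis.

    Axis "compartment": altered = switch class A2B or B2A, stable = A2A/B2B.
    Axis "tad": altered vs stable TAD at the gene midpoint.
    Axis "loop": gene at a specific-loop anchor vs not.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")

    def strata(a: GeneAnnotation) -> str | None:
        if axis == "compartment":
            if a.switch_class in ("A2B", "B2A"):
                return "altered"
            if a.switch_class in ("A2A", "B2B"):
                return "stable"
            return None
        if axis == "tad":
            return a.tad_status if a.tad_status in ("altered", "stable") else None
        return "altered" if a.at_loop_anchor else "stable"

    cells = {("altered", True): 0, ("altered", False): 0, ("stable", True): 0, ("stable", False): 0}
    for a in annotations:
        s = strata(a)
        if s is None:
            continue
        cells[(s, a.de_status != "not-DE")] += 1

    table = (
        (cells[("altered", True)], cells[("altered", False)]),
        (cells[("stable", True)], cells[("stable", False)]),
    )
    ratios, flags = {}, {}
    for name, (deg, ndeg) in zip(("altered", "stable"), table):
        r, f = _ratio(deg, ndeg)
        ratios[f"deg_ndeg_{name}"] = r
        flags[f"deg_ndeg_{name}"] = f
    if table[0][0] + table[0][1] == 0 or table[1][0] + table[1][1] == 0:
        # empty stratum: report counts, no test
        return ContingencyResult(
            ("altered", "stable"), ("DEG", "NDEG"), table, ratios, flags,
            float("nan"), 1, float("nan"),
        )
    stat, dof, p = pearson_chi2(table)
    return ContingencyResult(("altered", "stable"), ("DEG", "NDEG"), table, ratios, flags, stat, dof, p)


# ---------------------------------------------------------------------------
# Report bundle


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, ContingencyResult):
        return x.to_dict()
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return v if np.isfinite(v) else None
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    return x


def build_report(sections: dict[str, object]) -> dict:
    """Assemble the structured run summary; absent stages are marked "not run"."""
    expected = (
        "parameters",
        "normalize",
        "ide",
        "compartments",
        "tads",
        "loops",
        "translocations",
        "sv_overlap",
        "expression",
    )
    report: dict[str, object] = {}
    for key in expected:
        if key in sections and sections[key] is not None:
            report[key] = _jsonable(sections[key])
        else:
            report[key] = "not run"
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
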