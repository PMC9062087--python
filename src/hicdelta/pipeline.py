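"""Full comparative run: normalization through integration, with caching.

Stage order follows the logic that rearranged trans signal must not leak
into structural comparisons: load -> ICE -> translocation scan +
double-confirmation -> masking -> compartments / decay / TADs / loops ->
expression integration -> report.  Each stage writes its summary under the
output directory as ``stage_<name>.json``; the final report bundles them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import compartments as comp_mod
from . import insulation_tads as tad_mod
from . import integration as int_mod
from . import loops_compare as loop_mod
from . import matrix_metrics as mm
from . import translocations_sv as tr_mod
from .contact_io import (
    bin_genome,
    read_bedpe_loops,
    read_breakpoints,
    read_gene_table,
    read_matrix,
    read_sv_table,
)
from .synthetic_data import CONDITIONS, SyntheticTruth

log = logging.getLogger("hicdelta")

__all__ = ["RunConfig", "PipelineRun", "run_full"]


@dataclass
class RunConfig:
    """Paths, resolutions, thresholds and the seed of one comparative run.

    Inputs are resolved inside ``data_dir`` by the emitter's naming scheme
    (``<condition>_<resolution>.matrix`` etc.); ``out_dir`` receives stage
    caches and the report.
    """

    data_dir: str = "."
    out_dir: str = "out"
    compartment_res: int = 500_000
    tad_res: int = 50_000
    loop_res: int = 10_000
    trans_res: int = 40_000
    ice_max_iter: int = 200
    ice_tol: float = 1e-5
    coverage_filter_fraction: float = 0.02
    insulation_window: int = 10
    delta_window: int = 2
    boundary_strength: float = 0.5
    boundary_tolerance: int = 1
    loop_tolerance: int = 0
    loop_mode: str = "joint"
    trans_fold: float = 4.0
    trans_min_span: int = 10
    edge_tolerance: int = 1
    padj_max: float = 0.05
    lfc_min: float = 1.0
    mask_translocations: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def matrix_paths(self, condition: str, res: int) -> tuple[Path, Path]:
        d = Path(self.data_dir)
        return d / f"{condition}_{res}.matrix", d / f"{condition}_{res}_abs.bed"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class PipelineRun:
    """Holds in-memory stage products and writes per-stage caches."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.normalized: dict[tuple[str, int], object] = {}
        self.sections: dict[str, object] = {"parameters": self._parameters()}
        self.events: list = []
        self._switch_track = None
        self._tad_sets = None
        self._boundary_cmp = None
        self._loop_cmp = None
        self._tumor_boundaries = None

    def _parameters(self) -> dict:
        return {f.name: getattr(self.cfg, f.name) for f in fields(RunConfig)}

    def _cache(self, name: str, payload: object) -> None:
        self.sections[name] = payload
        with open(self.out / f"stage_{name}.json", "w") as fh:
            json.dump(int_mod._jsonable(payload), fh, indent=2, sort_keys=True)

    # -- stages ------------------------------------------------------------

    def normalize(self) -> None:
        cfg = self.cfg
        for cond in CONDITIONS:
            for res in sorted({cfg.compartment_res, cfg.tad_res, cfg.trans_res}):
                mpath, bpath = cfg.matrix_paths(cond, res)
                m = read_matrix(mpath, bpath)
                result = mm.ice_normalize(
                    m, cfg.ice_max_iter, cfg.ice_tol, cfg.coverage_filter_fraction
                )
                log.info("ICE %s@%d: converged=%s iters=%d", cond, res, result.converged, result.n_iter)
                self.normalized[(cond, res)] = result
        self._cache(
            "normalize",
            {
                f"{cond}_{res}": {"converged": r.converged, "n_iter": r.n_iter}
                for (cond, res), r in sorted(self.normalized.items())
            },
        )

    def translocations(self) -> None:
        cfg = self.cfg
        tumor = self.normalized[("tumor", cfg.trans_res)].matrix
        events = tr_mod.scan_all_pairs(tumor, cfg.trans_fold, cfg.trans_min_span)
        bp_path = Path(cfg.data_dir) / "breakpoints.tsv"
        if bp_path.exists():
            bps = read_breakpoints(bp_path, tumor.bins.genome)
            events = tr_mod.double_confirm(events, bps, cfg.trans_res, cfg.edge_tolerance)
        self.events = events
        if cfg.mask_translocations:
            for key, r in list(self.normalized.items()):
                masked = tr_mod.mask_events(r.matrix, events)
                self.normalized[key] = r._replace(matrix=masked)
        self._cache(
            "translocations",
            [
                {
                    "chrom_a": e.chrom_a, "start_a": e.start_a, "end_a": e.end_a,
                    "chrom_b": e.chrom_b, "start_b": e.start_b, "end_b": e.end_b,
                    "fold": e.fold, "status": e.status,
                }
                for e in self.events
            ],
        )

    def _reference_track(self, bins, condition: str = "normal") -> np.ndarray:
        truth_path = Path(self.cfg.data_dir) / "truth.json"
        if truth_path.exists():
            with open(truth_path) as fh:
                truth = SyntheticTruth.from_dict(json.load(fh))
            return truth.activity_track(bins, condition)
        gene_path = Path(self.cfg.data_dir) / "genes.tsv"
        if gene_path.exists():
            genes = read_gene_table(gene_path, bins.genome,
                                    padj_max=self.cfg.padj_max, lfc_min=self.cfg.lfc_min)
            track = np.zeros(bins.n_bins)
            for g in genes:
                track[bins.position_to_bin(g.chrom, g.midpoint)] += 1
            return track
        raise FileNotFoundError("no reference activity source (truth.json or genes.tsv)")

    def compartments(self) -> None:
        cfg = self.cfg
        profiles = {}
        for cond in CONDITIONS:
            m = self.normalized[(cond, cfg.compartment_res)].matrix
            profiles[cond] = comp_mod.call_compartments(m, self._reference_track(m.bins, cond))
        track = comp_mod.classify_switch(profiles["normal"], profiles["tumor"])
        self._switch_track = track
        ratios = comp_mod.activation_ratio(track)
        frame = track.bins.to_frame()
        frame["pc1_normal"] = profiles["normal"].pc1
        frame["pc1_tumor"] = profiles["tumor"].pc1
        frame["class"] = track.classes
        frame.to_csv(self.out / "compartment_switch.tsv", sep="\t", index=False)
        self._cache(
            "compartments",
            {
                "fractions_of_classified": track.fractions(),
                "fractions_of_genome": track.fractions_of_genome(),
                "activation_ratio": {
                    k: {"value": v.value, "flag": v.flag} for k, v in ratios.items()
                },
            },
        )

    def ide(self) -> None:
        cfg = self.cfg
        out = {}
        for cond in CONDITIONS:
            m_tad = self.normalized[(cond, cfg.tad_res)].matrix
            curve = mm.decay_curve_and_ide(m_tad)
            ct = mm.cis_trans_ratio(self.normalized[(cond, cfg.trans_res)].matrix)
            out[cond] = {
                "exponents": {
                    f"{lo:g}-{hi:g}": exp for (lo, hi), (exp, _) in zip(curve.segments, curve.exponents)
                },
                "cis_total": ct.cis_total,
                "trans_total": ct.trans_total,
                "trans_fraction": ct.trans_fraction,
            }
        cluster = mm.chromosome_cluster(self.normalized[("tumor", cfg.compartment_res)].matrix)
        out["chromosome_leaf_order"] = list(cluster.leaf_order)
        self._cache("ide", out)

    def tads(self) -> None:
        cfg = self.cfg
        tracks, bsets = {}, {}
        for cond in CONDITIONS:
            m = self.normalized[(cond, cfg.tad_res)].matrix
            tr = tad_mod.insulation_score(m, cfg.insulation_window)
            tracks[cond] = tr
            bsets[cond] = tad_mod.call_boundaries(tr, cfg.delta_window, cfg.boundary_strength)
        cmpres = tad_mod.compare_boundaries(
            bsets["normal"], bsets["tumor"], cfg.boundary_tolerance
        )
        tads_n = tad_mod.tads_from_boundaries(bsets["normal"])
        tads_t = tad_mod.tads_from_boundaries(bsets["tumor"])
        alt_n, alt_t = tad_mod.altered_tads(tads_n, tads_t, cmpres)
        self._tad_sets = (alt_n, alt_t)
        self._boundary_cmp = cmpres
        self._tumor_boundaries = bsets["tumor"]
        stable_sizes = [t.size_bp(cfg.tad_res) for ts in (alt_n, alt_t) for t in ts.tads if not t.altered]
        altered_sizes = [t.size_bp(cfg.tad_res) for ts in (alt_n, alt_t) for t in ts.tads if t.altered]
        size_stats = None
        if stable_sizes and altered_sizes:
            st = tad_mod.tad_size_stats(altered_sizes, stable_sizes)
            size_stats = {"median_altered": st.median_a, "median_stable": st.median_b,
                          "statistic": st.statistic, "p_value": st.p_value}
        self._cache(
            "tads",
            {
                "n_boundaries_normal": len(bsets["normal"]),
                "n_boundaries_tumor": len(bsets["tumor"]),
                "n_shared": len(cmpres.shared),
                "n_specific_normal": len(cmpres.specific_a),
                "n_specific_tumor": len(cmpres.specific_b),
                "median_tad_bp": float(np.median(np.concatenate([tads_n.sizes_bp(), tads_t.sizes_bp()])))
                if tads_n.tads or tads_t.tads else None,
                "altered_fraction_by_chrom_tumor": alt_t.altered_fraction_by_chrom(),
                "size_stats": size_stats,
            },
        )

    def loops(self) -> bool:
        cfg = self.cfg
        paths = {c: Path(cfg.data_dir) / f"{c}_loops.bedpe" for c in CONDITIONS}
        if not all(p.exists() for p in paths.values()):
            log.warning("loop files missing; loop stage skipped")
            return False
        sets = {c: read_bedpe_loops(p).loops for c, p in paths.items()}
        cmpres = loop_mod.specific_loops(
            sets["normal"], sets["tumor"], cfg.loop_tolerance, cfg.loop_res, cfg.loop_mode
        )
        self._loop_cmp = cmpres
        stats = loop_mod.loop_length_stats(sets["normal"], sets["tumor"])
        self._cache(
            "loops",
            {
                "n_normal": len(sets["normal"]),
                "n_tumor": len(sets["tumor"]),
                "n_shared": len(cmpres.shared),
                "n_specific_normal": len(cmpres.specific_a),
                "n_specific_tumor": len(cmpres.specific_b),
                "length_stats": dict(stats._asdict()),
                "counts_by_chrom": cmpres.counts_by_chrom(),
            },
        )
        return True

    def sv_overlap(self) -> bool:
        cfg = self.cfg
        sv_path = Path(cfg.data_dir) / "tumor_sv.bed"
        if not sv_path.exists() or self._tumor_boundaries is None:
            return False
        genome = self._tumor_boundaries.bins.genome
        svs = read_sv_table(sv_path, genome)
        bins = self._tumor_boundaries.bins
        feats, altered = [], []
        spec_bins = {b.bin for b in self._boundary_cmp.specific_b}
        for b in self._tumor_boundaries.boundaries:
            feats.append((bins.chrom_of(b.bin), int(bins.starts[b.bin]), int(bins.ends[b.bin])))
            altered.append(b.bin in spec_bins)
        payload = {}
        if feats:
            payload["boundaries"] = [
                dict(sv_type=r.sv_type, fraction_all=r.fraction_all,
                     fraction_altered=r.fraction_altered, chi2=r.chi2, p_value=r.p_value)
                for r in tr_mod.sv_overlap_enrichment(feats, np.array(altered), svs)
            ]
        if self._loop_cmp is not None:
            anchors = loop_mod.anchor_intervals(
                [l for l, _ in self._loop_cmp.shared] + list(self._loop_cmp.specific_b)
            )
            spec_anchors = set(loop_mod.anchor_intervals(self._loop_cmp.specific_b))
            aflags = np.array([a in spec_anchors for a in anchors])
            if anchors:
                payload["loop_anchors"] = [
                    dict(sv_type=r.sv_type, fraction_all=r.fraction_all,
                         fraction_altered=r.fraction_altered, chi2=r.chi2, p_value=r.p_value)
                    for r in tr_mod.sv_overlap_enrichment(anchors, aflags, svs)
                ]
        self._cache("sv_overlap", payload)
        return True

    def integrate(self) -> bool:
        cfg = self.cfg
        gene_path = Path(cfg.data_dir) / "genes.tsv"
        if not gene_path.exists() or self._switch_track is None:
            return False
        genes = read_gene_table(gene_path, self._switch_track.bins.genome,
                                padj_max=cfg.padj_max, lfc_min=cfg.lfc_min)
        ann = int_mod.annotate_genes(genes, self._switch_track, self._tad_sets, self._loop_cmp)
        updown = int_mod.updown_by_class(ann)
        payload = {"updown_by_class": {k: v for k, v in updown.items()}}
        for axis in int_mod.AXES:
            payload[f"deg_by_{axis}"] = int_mod.deg_by_alteration(ann, axis)
        self._cache("expression", payload)
        return True

    # -- driver ------------------------------------------------------------

    def run_full(self) -> dict:
        order = [
            ("normalize", self.normalize),
            ("translocations", self.translocations),
            ("compartments", self.compartments),
            ("ide", self.ide),
            ("tads", self.tads),
            ("loops", self.loops),
            ("sv_overlap", self.sv_overlap),
            ("expression", self.integrate),
        ]
        for name, fn in order:
            log.info("stage %s", name)
            try:
                fn()
            except Exception as exc:  # halt with a stage-named error
                raise StageError(name, exc) from exc
        report = int_mod.build_report(self.sections)
        int_mod.write_report(report, self.out / "report.json")
        return report


def run_full(config: RunConfig) -> dict:
    """Run every stage in order and write ``report.json`` under out_dir."""
    return PipelineRun(config).run_full()
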