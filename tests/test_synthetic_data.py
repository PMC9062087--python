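"""Generator contracts: determinism, decay, depth, planted structures, expression."""

import json

import numpy as np
import pytest

from hicdelta.contact_io import GenomeSpec, bin_genome, read_matrix
from hicdelta.synthetic_data import (
    ExpressionEffects,
    SyntheticConfig,
    SyntheticTranslocation,
    SyntheticTruth,
    emit_files,
    generate_expression,
    generate_pair,
)


def pure_power_law_config(seed=0, **kw):
    base = dict(
        plaid_strength=1.0,
        tad_enrichment=1.0,
        loops_per_chrom=0,
        n_loop_add=0,
        n_loop_remove=0,
        bias_range=(1.0, 1.0),
        translocations=(),
        seed=seed,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            SyntheticConfig(alpha=0.5)
        with pytest.raises(ValueError, match="plaid"):
            SyntheticConfig(plaid_strength=0)
        with pytest.raises(ValueError, match="depth"):
            SyntheticConfig(depth=0)

    def test_translocation_span_beyond_chromosome_rejected(self):
        tr = SyntheticTranslocation("chr2", 0, 99_000_000, "chr3", 0, 1_000_000)
        with pytest.raises(ValueError, match="exceeds chromosome"):
            SyntheticConfig(translocations=(tr,))

    def test_boundaries_closer_than_two_bins_rejected(self):
        cfg = SyntheticConfig(tad_boundaries={"chr1": [1_000_000, 1_050_000]})
        with pytest.raises(ValueError, match="closer than 2 bins"):
            generate_pair(cfg)


class TestGeneratePair:
    def test_same_seed_gives_identical_matrices(self):
        a = generate_pair(SyntheticConfig(seed=7))
        b = generate_pair(SyntheticConfig(seed=7))
        for key in a.matrices:
            assert (a.matrices[key].data != b.matrices[key].data).nnz == 0
        assert a.truth.to_dict() == b.truth.to_dict()

    def test_power_law_decay_slope(self):
        ds = generate_pair(pure_power_law_config(seed=1, depth=2e6))
        m = ds.matrices[("normal", 50_000)]
        block, _ = m.cis_block("chr1")
        n = block.shape[0]
        dists = np.arange(2, 60)
        means = np.array([np.diagonal(block, d).mean() for d in dists])
        slope = np.polyfit(np.log10(dists), np.log10(means), 1)[0]
        assert slope == pytest.approx(-1.2, abs=0.1)

    def test_total_counts_near_configured_depth(self):
        cfg = SyntheticConfig(seed=2)
        ds = generate_pair(cfg)
        for m in ds.matrices.values():
            assert abs(m.total() - cfg.depth) <= 3 * np.sqrt(cfg.depth)

    def test_planted_translocation_fold_in_range(self):
        cfg = SyntheticConfig(seed=3)
        ds = generate_pair(cfg)
        tr = cfg.translocations[0]
        m = ds.matrices[("tumor", 40_000)]
        block = m.trans_block(tr.chrom_a, tr.chrom_b)
        r0, r1 = tr.start_a // 40_000, tr.end_a // 40_000
        c0, c1 = tr.start_b // 40_000, tr.end_b // 40_000
        inside = block[r0:r1, c0:c1].mean()
        outside = np.concatenate([block[:r0].ravel(), block[r1:].ravel()]).mean()
        assert 6.0 <= inside / outside <= 10.0

    def test_tumor_differs_only_in_configured_ways(self):
        cfg = SyntheticConfig(seed=4)
        ds = generate_pair(cfg)
        t = ds.truth
        assert t.labels["normal"] != t.labels["tumor"]
        classes = set(t.switch_classes)
        assert {"A2B", "B2A"} <= classes
        assert t.boundaries["normal"] != t.boundaries["tumor"]
        assert t.loops["normal"] != t.loops["tumor"]

    def test_planted_loops_are_local_maxima_of_expected_matrix(self):
        # pure decay + loop dots, so the dot is the only local structure
        cfg = pure_power_law_config(seed=5, loops_per_chrom=25, n_loop_add=8, n_loop_remove=8)
        ds = generate_pair(cfg, noiseless=True)
        m = ds.matrices[("normal", 50_000)]
        loops = ds.truth.loops_of("normal")
        pairs = [(lp.chrom, lp.start1 // 50_000, lp.start2 // 50_000) for lp in loops]
        checked = 0
        ok = 0
        for chrom, i, j in pairs:
            block, _ = m.cis_block(chrom)
            n = block.shape[0]
            # near the diagonal the decay gradient legitimately exceeds the
            # dot within the patch; require spans where the dot dominates
            if abs(i - j) < 8 or min(i, j) < 2 or max(i, j) > n - 3:
                continue
            near = [
                p for p in pairs
                if p != (chrom, i, j) and p[0] == chrom and abs(p[1] - i) <= 4 and abs(p[2] - j) <= 4
            ]
            if near:
                continue  # overlapping dots shift the local maximum
            block, _ = m.cis_block(chrom)
            patch = block[i - 2 : i + 3, j - 2 : j + 3]
            checked += 1
            ok += patch[2, 2] >= patch.max()
        assert checked >= 10
        assert ok == checked


class TestExpression:
    def test_null_effects_leave_few_de_calls(self, default_dataset):
        effects = ExpressionEffects(b2a=0, a2b=0, tad_altered=0, loop_anchor=0)
        genes = generate_expression(
            default_dataset.truth, default_dataset.config.genome, effects, seed=11
        )
        de_fraction = np.mean([g.status != "not-DE" for g in genes])
        assert de_fraction < 0.10

    def test_b2a_shift_biases_up_down_ratio(self, default_dataset):
        genes = generate_expression(
            default_dataset.truth,
            default_dataset.config.genome,
            ExpressionEffects(b2a=2.0, sigma=0.5),
            seed=12,
        )
        b2a = [g for g in genes if g.gene_id.startswith("G_b2a")]
        up = sum(g.status == "up" for g in b2a)
        down = sum(g.status == "down" for g in b2a)
        assert up > down

    def test_stable_class_centered_at_zero(self, default_dataset):
        genes = generate_expression(
            default_dataset.truth, default_dataset.config.genome, ExpressionEffects(), seed=13
        )
        stable = [g.log2fc for g in genes if g.gene_id.startswith("G_stable")]
        assert abs(np.median(stable)) < 0.1

    def test_gene_classes_recorded_in_truth(self, default_dataset):
        genes = generate_expression(
            default_dataset.truth, default_dataset.config.genome, ExpressionEffects(), seed=14
        )
        assert all(g.gene_id in default_dataset.truth.gene_classes for g in genes)


class TestEmit:
    def test_emitted_files_load_and_manifest_is_reproducible(self, tmp_path):
        cfg = SyntheticConfig(seed=9)
        ds = generate_pair(cfg)
        ds.genes = generate_expression(ds.truth, cfg.genome, ExpressionEffects(), seed=9)
        m1 = emit_files(ds, tmp_path / "a")
        m2 = emit_files(ds, tmp_path / "b")
        assert m1["sha256"] == m2["sha256"]
        for res in (40_000, 50_000, 500_000):
            for cond in ("normal", "tumor"):
                assert f"matrix_{cond}_{res}" in m1["paths"]
        back = read_matrix(tmp_path / "a" / "normal_50000.matrix", tmp_path / "a" / "normal_50000_abs.bed")
        assert back.total() == ds.matrices[("normal", 50_000)].total()

    def test_truth_json_round_trips(self, tmp_path):
        cfg = SyntheticConfig(seed=10)
        ds = generate_pair(cfg)
        emit_files(ds, tmp_path)
        with open(tmp_path / "truth.json") as fh:
            loaded = SyntheticTruth.from_dict(json.load(fh))
        assert loaded.to_dict() == ds.truth.to_dict()
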