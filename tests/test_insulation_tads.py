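"""Insulation scores, boundary calling, and TAD comparison."""

import numpy as np
import pytest

from hicdelta.contact_io import ContactMatrix, GenomeSpec, bin_genome
from hicdelta.insulation_tads import (
    Boundary,
    BoundarySet,
    InsulationTrack,
    altered_tads,
    boundary_precision_recall,
    call_boundaries,
    compare_boundaries,
    delta_insulation,
    insulation_score,
    tad_size_stats,
    tads_from_boundaries,
)
from hicdelta.matrix_metrics import ice_normalize
from hicdelta.synthetic_data import SyntheticConfig, generate_pair


def _track_from_norm(norm, res=50_000):
    bins = bin_genome(GenomeSpec.from_dict({"chr1": len(norm) * res}), res)
    return InsulationTrack(bins, np.asarray(norm, float), np.asarray(norm, float), 10)


def _bset(bins, positions, strength=1.0):
    return BoundarySet(bins, tuple(Boundary(int(b), strength) for b in sorted(positions)))


class TestInsulationScore:
    def test_uniform_matrix_gives_zero_normalized_score(self):
        n = 60
        bins = bin_genome(GenomeSpec.from_dict({"chr1": n * 50_000}), 50_000)
        m = ContactMatrix.from_dense(bins, np.ones((n, n)), "normalized")
        track = insulation_score(m, 10)
        valid = track.valid()
        assert valid.any()
        assert np.allclose(track.norm[valid], 0.0)
        # undefined within w bins of the edges
        assert not valid[:10].any() and not valid[-10:].any()

    def test_two_block_matrix_minimum_at_junction(self):
        n = 60
        dense = np.ones((n, n)) * 1e-6
        dense[:30, :30] = 1.0
        dense[30:, 30:] = 1.0
        bins = bin_genome(GenomeSpec.from_dict({"chr1": n * 50_000}), 50_000)
        m = ContactMatrix.from_dense(bins, dense, "normalized")
        track = insulation_score(m, 10)
        assert np.nanargmin(track.norm) in (29, 30)

    def test_short_chromosome_all_na(self):
        bins = bin_genome(GenomeSpec.from_dict({"chr1": 15 * 50_000}), 50_000)
        m = ContactMatrix.from_dense(bins, np.ones((15, 15)), "normalized")
        assert not insulation_score(m, 10).valid().any()

    def test_planted_boundaries_are_score_minima(self):
        # 12 sparse boundaries at enrichment 3: the score valley localizes
        # each one to within a bin for at least 90% of them
        cfg = SyntheticConfig(
            genome=GenomeSpec(("chr1",), (30_000_000,)),
            plaid_strength=1.0,
            loops_per_chrom=0, n_loop_add=0, n_loop_remove=0,
            tad_boundaries={"chr1": [int(2.3e6 * (i + 1)) for i in range(12)]},
            n_boundary_remove=0, n_boundary_add=0, n_boundary_move=0,
            translocations=(), depth=1.2e6, seed=4,
        )
        ds = generate_pair(cfg)
        iced = ice_normalize(ds.matrices[("normal", 50_000)])
        track = insulation_score(iced.matrix, 10)
        truth_bins = np.array(ds.truth.boundary_bins("normal", iced.matrix.bins))
        hits = 0
        for t in truth_bins:
            window = track.norm[t - 3 : t + 4]
            local_min = np.nanargmin(window) + t - 3
            hits += abs(local_min - t) <= 1
        assert hits / len(truth_bins) >= 0.90


class TestCallBoundaries:
    def test_monotone_track_has_no_boundaries(self):
        track = _track_from_norm(np.linspace(-1, 1, 80))
        assert len(call_boundaries(track)) == 0

    def test_single_sharp_valley_located_exactly(self):
        norm = np.zeros(80)
        norm[40] = -1.0
        bs = call_boundaries(_track_from_norm(norm), 2, 0.1)
        assert [b.bin for b in bs.boundaries] == [40]

    def test_strength_threshold_keeps_only_deep_valley(self):
        # single-bin valleys of depth 0.05 and 0.5; after 3-bin smoothing the
        # delta swing is 2/3 of the depth, so threshold 0.1 keeps only the deep one
        norm = np.zeros(100)
        norm[30] = -0.05
        norm[70] = -0.5
        bs = call_boundaries(_track_from_norm(norm), 2, 0.1)
        assert [b.bin for b in bs.boundaries] == [70]
        assert bs.boundaries[0].strength == pytest.approx(0.5 * 2 / 3, abs=1e-9)

    def test_generator_boundary_recovery(self, default_dataset, iced_50):
        for cond in ("normal", "tumor"):
            bs = call_boundaries(insulation_score(iced_50[cond].matrix, 10))
            truth = default_dataset.truth.boundary_bins(cond, iced_50[cond].matrix.bins)
            precision, recall = boundary_precision_recall(bs, truth, 1)
            assert precision >= 0.9 and recall >= 0.8

    def test_boundary_count_stable_under_matrix_scaling(self, iced_50):
        m = iced_50["normal"].matrix
        bs1 = call_boundaries(insulation_score(m, 10))
        bs2 = call_boundaries(insulation_score(m.scaled(5.0), 10))
        assert bs1.bin_indices().tolist() == bs2.bin_indices().tolist()


class TestCompare:
    def test_identical_sets_fully_shared(self, one_chrom_bins):
        a = _bset(one_chrom_bins, [10, 50, 90])
        cmpres = compare_boundaries(a, a, 1)
        assert len(cmpres.shared) == 3 and not cmpres.specific_a and not cmpres.specific_b
        ta, tb = altered_tads(tads_from_boundaries(a), tads_from_boundaries(a), cmpres)
        assert not any(t.altered for t in ta.tads + tb.tads)

    def test_disjoint_sets_all_specific_all_altered(self, one_chrom_bins):
        a = _bset(one_chrom_bins, [100, 200, 300])
        b = _bset(one_chrom_bins, [150, 250, 350])
        cmpres = compare_boundaries(a, b, 1)
        assert not cmpres.shared
        ta, tb = altered_tads(tads_from_boundaries(a), tads_from_boundaries(b), cmpres)
        assert all(t.altered for t in ta.tads + tb.tads)

    def test_hand_matching_example(self, one_chrom_bins):
        a = _bset(one_chrom_bins, [10, 50, 90])
        b = _bset(one_chrom_bins, [11, 50, 300])
        cmpres = compare_boundaries(a, b, 1)
        assert [(x.bin, y.bin) for x, y in sorted(cmpres.shared)] == [(10, 11), (50, 50)]
        assert [x.bin for x in cmpres.specific_a] == [90]
        assert [x.bin for x in cmpres.specific_b] == [300]

    def test_symmetry_mirrors_specific_sets(self, one_chrom_bins):
        rng = np.random.default_rng(3)
        a = _bset(one_chrom_bins, rng.choice(500, 12, replace=False))
        b = _bset(one_chrom_bins, rng.choice(500, 15, replace=False))
        fwd = compare_boundaries(a, b, 1)
        rev = compare_boundaries(b, a, 1)
        assert {x.bin for x in fwd.specific_a} == {x.bin for x in rev.specific_b}
        assert {x.bin for x in fwd.specific_b} == {x.bin for x in rev.specific_a}
        assert len(fwd.shared) == len(rev.shared)

    def test_planted_alterations_partition_matches_truth(self):
        cfg = SyntheticConfig(seed=6)
        ds = generate_pair(cfg)
        bins = bin_genome(cfg.genome, cfg.tad_res)
        bn = _bset(bins, ds.truth.boundary_bins("normal", bins))
        bt = _bset(bins, ds.truth.boundary_bins("tumor", bins))
        cmpres = compare_boundaries(bn, bt, 0)
        spec = ds.truth.specific_boundaries()
        want_a = {
            bins.position_to_bin(c, p)
            for c, ps in spec["normal"].items()
            for p in ps
        }
        want_b = {
            bins.position_to_bin(c, p)
            for c, ps in spec["tumor"].items()
            for p in ps
        }
        assert {b.bin for b in cmpres.specific_a} == want_a
        assert {b.bin for b in cmpres.specific_b} == want_b


class TestDeltaAndSizes:
    def test_self_difference_is_zero(self, iced_50):
        track = insulation_score(iced_50["normal"].matrix, 10)
        d = delta_insulation(track, track)
        assert np.allclose(d[np.isfinite(d)], 0.0)

    def test_tad_size_formula(self, one_chrom_bins):
        ts = tads_from_boundaries(_bset(one_chrom_bins, [10, 25, 100]))
        assert [t.size_bp(one_chrom_bins.resolution) for t in ts.tads] == [
            15 * 50_000,
            75 * 50_000,
        ]

    def test_ranksum_detects_doubled_sizes(self):
        rng = np.random.default_rng(5)
        stable = rng.lognormal(np.log(600_000), 0.3, 40)
        altered = 2 * rng.lognormal(np.log(600_000), 0.3, 40)
        st = tad_size_stats(altered, stable)
        assert st.p_value < 0.05 and st.median_a > st.median_b
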