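"""ICE balancing, expected/OE, cis-trans ratios, decay fits, clustering."""

import numpy as np
import pytest

from hicdelta.contact_io import ContactMatrix, GenomeSpec, bin_genome
from hicdelta.matrix_metrics import (
    chromosome_cluster,
    cis_trans_ratio,
    cumulative_cis_by_distance,
    decay_curve_and_ide,
    expected_by_distance,
    ice_normalize,
    observed_over_expected,
    oe_block,
)
from hicdelta.compartments import call_compartments


def _one_chrom_matrix(dense, res=50_000, kind="raw"):
    n = dense.shape[0]
    bins = bin_genome(GenomeSpec.from_dict({"chr1": n * res}), res)
    return ContactMatrix.from_dense(bins, dense, kind)


class TestIce:
    def test_balanced_matrix_is_fixed_point(self):
        n = 30
        dense = np.ones((n, n))
        res = ice_normalize(_one_chrom_matrix(dense))
        assert res.converged and res.n_iter == 1
        assert np.allclose(res.bias.values[~res.bias.mask], 1.0)

    def test_recovers_planted_bias(self):
        # counts = b_i * b_j * T_ij with T balanced (all off-diagonal equal)
        rng = np.random.default_rng(0)
        n = 80
        b = np.exp(rng.uniform(np.log(0.5), np.log(2.0), n))
        t = np.ones((n, n))
        counts = np.outer(b, b) * t
        res = ice_normalize(_one_chrom_matrix(counts), tol=1e-12, max_iter=500)
        ok = ~res.bias.mask
        corr = np.corrcoef(np.log(res.bias.values[ok]), np.log(b[ok]))[0, 1]
        assert corr > 0.999

    def test_zero_coverage_bin_masked_and_marginals_flat(self):
        rng = np.random.default_rng(1)
        n = 50
        dense = rng.poisson(20, (n, n)).astype(float)
        dense = np.triu(dense) + np.triu(dense, 1).T
        dense[7, :] = 0.0
        dense[:, 7] = 0.0
        res = ice_normalize(_one_chrom_matrix(dense))
        assert res.bias.mask[7]
        w = res.matrix.dense()
        marg = w.sum(axis=0)[~res.bias.mask]
        assert marg.std() / marg.mean() < 1e-4

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        n = 60
        dense = rng.poisson(15, (n, n)).astype(float)
        dense = np.triu(dense) + np.triu(dense, 1).T
        first = ice_normalize(_one_chrom_matrix(dense))
        second = ice_normalize(
            ContactMatrix(first.matrix.bins, first.matrix.data.copy(), "raw"),
        )
        a, b = first.matrix.dense(), second.matrix.dense()
        ok = ~(first.bias.mask | second.bias.mask)
        rel = np.abs(a[np.ix_(ok, ok)] - b[np.ix_(ok, ok)]) / (a[np.ix_(ok, ok)] + 1e-12)
        assert np.nanmedian(rel) < 1e-3

    def test_all_masked_raises(self):
        m = _one_chrom_matrix(np.zeros((10, 10)))
        with pytest.raises(ValueError, match="masked"):
            ice_normalize(m)


class TestExpectedOE:
    def test_distance_function_gives_unit_oe(self):
        n = 40
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        dense = 1.0 / (1 + d)
        m = _one_chrom_matrix(dense, kind="normalized")
        oe, mask = oe_block(m, "chr1")
        assert np.allclose(oe[~mask][:, ~mask], 1.0)

    def test_expected_single_entry_hand_count(self):
        # one nonzero at distance 3 in a 6-bin chromosome: 3 pairs at d=3
        dense = np.zeros((6, 6))
        dense[0, 3] = dense[3, 0] = 9.0
        m = _one_chrom_matrix(dense, kind="normalized")
        e = expected_by_distance(m, "chr1")
        assert e[3] == pytest.approx(9.0 / 3)

    def test_masked_bin_excluded_from_expected(self):
        n = 10
        dense = np.ones((n, n))
        m = _one_chrom_matrix(dense, kind="normalized")
        m.mask[4] = True
        e_masked = expected_by_distance(m, "chr1")
        # masked bin contributes to neither numerator nor denominator
        assert np.allclose(e_masked[1:], 1.0, equal_nan=True)
        oe, _ = oe_block(m, "chr1")
        assert (oe[4, :] == 0).all() and (oe[:, 4] == 0).all()


class TestCisTrans:
    def test_intra_only_gives_zero_trans(self):
        m = _one_chrom_matrix(np.ones((20, 20)))
        r = cis_trans_ratio(m)
        assert r.trans_total == 0 and r.trans_fraction == 0

    def test_arithmetic(self):
        bins = bin_genome(GenomeSpec.from_dict({"a": 200, "b": 200}), 100)
        dense = np.zeros((4, 4))
        dense[0, 1] = 900.0   # cis on chromosome a
        dense[1, 2] = 100.0   # trans
        m = ContactMatrix.from_dense(bins, dense)
        r = cis_trans_ratio(m)
        assert (r.cis_total, r.trans_total, r.trans_fraction) == (900.0, 100.0, 0.10)

    def test_translocated_tumor_has_more_trans(self):
        from hicdelta.synthetic_data import SyntheticConfig, generate_pair

        # tumor differs from normal only by the planted translocation
        cfg = SyntheticConfig(
            seed=8, b2a_fraction=0.0, a2b_fraction=0.0,
            n_boundary_remove=0, n_boundary_add=0, n_boundary_move=0,
            n_loop_remove=0, n_loop_add=0,
        )
        ds = generate_pair(cfg, noiseless=True)
        n = cis_trans_ratio(ds.matrices[("normal", 40_000)])
        t = cis_trans_ratio(ds.matrices[("tumor", 40_000)])
        assert t.trans_fraction > n.trans_fraction


class TestDecay:
    def test_exact_power_law_recovered_to_machine_precision(self):
        n = 600
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
        dense = np.maximum(d, 1.0) ** -1.0
        m = _one_chrom_matrix(dense, kind="normalized")
        curve = decay_curve_and_ide(m)
        for exp, _ in curve.exponents:
            if np.isfinite(exp):
                assert exp == pytest.approx(-1.0, abs=1e-9)
        assert np.isfinite(curve.exponents[0][0])

    def test_flat_profile_gives_zero_exponent(self):
        dense = np.ones((400, 400))
        m = _one_chrom_matrix(dense, kind="normalized")
        curve = decay_curve_and_ide(m)
        assert curve.exponents[0][0] == pytest.approx(0.0, abs=1e-12)

    def test_short_segment_flagged_nan(self):
        # 20 bins at 50 kb: no distances beyond 1 Mb
        dense = np.ones((20, 20))
        m = _one_chrom_matrix(dense, kind="normalized")
        curve = decay_curve_and_ide(m)
        assert np.isnan(curve.exponents[2][0])

    def test_cumulative_curve_monotone_ends_at_one(self, iced_50):
        c = cumulative_cis_by_distance(iced_50["normal"].matrix)
        assert (np.diff(c.cumulative) >= 0).all()
        assert c.cumulative_fraction[-1] == pytest.approx(1.0)


class TestScaleInvariance:
    def test_oe_ide_and_compartments_invariant_under_count_scaling(self, default_dataset):
        m = default_dataset.matrices[("normal", 500_000)]
        truth_track = default_dataset.truth.activity_track(m.bins)
        res1 = ice_normalize(m)
        res2 = ice_normalize(m.scaled(3.7))
        oe1 = observed_over_expected(res1.matrix).dense()
        oe2 = observed_over_expected(res2.matrix).dense()
        assert np.allclose(oe1, oe2, rtol=1e-6, atol=1e-9)
        c1 = decay_curve_and_ide(res1.matrix)
        c2 = decay_curve_and_ide(res2.matrix)
        e1 = np.array([e for e, _ in c1.exponents])
        e2 = np.array([e for e, _ in c2.exponents])
        assert np.allclose(e1, e2, atol=1e-9, equal_nan=True)
        p1 = call_compartments(res1.matrix, truth_track)
        p2 = call_compartments(res2.matrix, truth_track)
        assert (p1.labels == p2.labels).all()


class TestChromosomeCluster:
    def _grouped_matrix(self, order=("a", "b", "c", "d")):
        groups = {"a": 0, "b": 0, "c": 1, "d": 1}
        genome = GenomeSpec(tuple(order), tuple([1000] * 4))
        bins = bin_genome(genome, 100)
        n = bins.n_bins
        dense = np.zeros((n, n))
        for i, ci in enumerate(order):
            for j, cj in enumerate(order):
                if i >= j:
                    continue
                lo_i, hi_i = bins.chrom_range(ci)
                lo_j, hi_j = bins.chrom_range(cj)
                val = 0.9 if groups[ci] == groups[cj] else 0.1
                dense[lo_i:hi_i, lo_j:hi_j] = val
        return ContactMatrix.from_dense(bins, dense, "normalized")

    def test_planted_groups_split_exactly(self):
        res = chromosome_cluster(self._grouped_matrix())
        assert res.partition(2) == frozenset({frozenset({"a", "b"}), frozenset({"c", "d"})})

    def test_partition_invariant_to_chromosome_order(self):
        res = chromosome_cluster(self._grouped_matrix(("c", "a", "d", "b")))
        assert res.partition(2) == frozenset({frozenset({"a", "b"}), frozenset({"c", "d"})})

    def test_requires_three_chromosomes(self):
        genome = GenomeSpec(("a", "b"), (1000, 1000))
        bins = bin_genome(genome, 100)
        m = ContactMatrix.from_dense(bins, np.ones((bins.n_bins, bins.n_bins)))
        with pytest.raises(ValueError):
            chromosome_cluster(m)
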