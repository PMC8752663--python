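import numpy as np
import pytest
from sklearn.base import clone

import alra
from alra import (
    ALRA,
    CountMatrix,
    NormalizedMatrix,
    alra as run_alra,
    apply_thresholds,
    compute_thresholds,
    lowrank_approximate,
    normalize,
    rescale_genes,
    restore_observed,
)

GENE_VALUES = np.array([-0.4, -0.1, 0.05, 0.3, 0.7, 1.2])


class TestLowRankApproximate:
    def test_exact_rank_identity(self):
        rng = np.random.default_rng(0)
        m = np.outer(rng.random(20) + 0.1, rng.random(15) + 0.1)
        lr = lowrank_approximate(m, k=1, seed=1)
        np.testing.assert_allclose(lr.values, m, atol=1e-8)

    def test_full_rank_identity(self):
        rng = np.random.default_rng(1)
        m = rng.random((8, 6)) + 0.05
        lr = lowrank_approximate(m, k=6, seed=1)
        np.testing.assert_allclose(lr.values, m, atol=1e-8)

    def test_matches_exact_truncated_svd_error(self):
        rng = np.random.default_rng(2)
        m = rng.standard_normal((80, 50))
        lr = lowrank_approximate(m, k=7, q=10, seed=3)
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        oracle = (u[:, :7] * s[:7]) @ vt[:7]
        err = np.linalg.norm(m - lr.values)
        err_oracle = np.linalg.norm(m - oracle)
        assert err == pytest.approx(err_oracle, rel=1e-6)

    def test_factors_reproduce_values(self):
        rng = np.random.default_rng(3)
        m = rng.random((30, 20))
        lr = lowrank_approximate(m, k=4, seed=4)
        np.testing.assert_allclose(lr.values, (lr.u * lr.s) @ lr.vt, atol=1e-8)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            lowrank_approximate(np.ones((4, 3)), k=5)

    def test_undetected_gene_column_is_exactly_zero(self):
        rng = np.random.default_rng(4)
        m = rng.random((40, 10))
        m[:, 3] = 0.0
        lr = lowrank_approximate(m, k=5, seed=5)
        assert np.all(lr.values[:, 3] == 0.0)


class TestThresholds:
    def test_interpolated_quantile_magnitude(self):
        lr = GENE_VALUES.reshape(-1, 1)
        ts = compute_thresholds(type("L", (), {"values": lr})(), p=0.001)
        assert ts.tau[0] == pytest.approx(0.3985, abs=1e-6)

    def test_all_positive_gene_keeps_minimum(self):
        lr = np.array([[0.2], [0.5], [0.9]])
        ts = compute_thresholds(type("L", (), {"values": lr})(), p=0.001)
        assert ts.tau[0] == pytest.approx(0.2, abs=1e-3)

    def test_symmetric_gene_threshold_mirrors_extreme(self):
        vals = np.linspace(-2.0, 2.0, 41).reshape(-1, 1)
        ts = compute_thresholds(type("L", (), {"values": vals})(), p=0.001)
        assert ts.tau[0] == pytest.approx(2.0, abs=0.01)

    def test_apply_zeroes_below_threshold_strictly(self):
        out = apply_thresholds(
            GENE_VALUES.reshape(-1, 1), alra.ThresholdSet(tau=np.array([0.3985]))
        )
        np.testing.assert_allclose(out.ravel(), [0, 0, 0, 0, 0.7, 1.2])

    def test_zero_threshold_keeps_nonnegatives(self):
        out = apply_thresholds(
            np.array([[-0.5], [0.0], [0.4]]), alra.ThresholdSet(tau=np.array([0.0]))
        )
        np.testing.assert_allclose(out.ravel(), [0, 0, 0.4])

    def test_value_exactly_at_threshold_survives(self):
        out = apply_thresholds(
            np.array([[0.3], [0.5]]), alra.ThresholdSet(tau=np.array([0.3]))
        )
        np.testing.assert_allclose(out.ravel(), [0.3, 0.5])

    def test_all_negative_gene_fully_zeroed(self):
        vals = -np.abs(np.random.default_rng(0).random((10, 1))) - 0.1
        ts = compute_thresholds(type("L", (), {"values": vals})())
        out = apply_thresholds(vals, ts)
        assert np.all(out == 0)


class TestRescaleGenes:
    def test_closed_form_affine_map(self):
        x = np.array([[2.0], [4.0], [0.0]])
        t = np.array([[0.5], [1.5], [2.5]])
        out = rescale_genes(t, x)
        np.testing.assert_allclose(
            out.ravel(), [3 - np.sqrt(2), 3.0, 3 + np.sqrt(2)], atol=1e-12
        )

    def test_already_matching_moments_is_identity(self):
        x = np.array([[1.0], [3.0], [0.0]])
        t = np.array([[1.0], [3.0], [0.0]])
        np.testing.assert_allclose(rescale_genes(t, x), t, atol=1e-12)

    def test_negative_mapped_values_clamped_to_zero(self):
        # x has a much larger coefficient of variation than t, so the affine
        # map drives t's smallest value below zero
        x = np.array([[0.1], [10.0], [0.0]])
        t = np.array([[5.0], [6.0], [7.0]])
        out, info = rescale_genes(t, x, return_info=True)
        assert np.all(out >= 0)
        assert info["clamped"].sum() > 0
        assert np.all(out[info["clamped"]] == 0)

    def test_degenerate_genes_left_unscaled(self):
        x = np.array([[1.0, 1.0], [0.0, 2.0]])  # gene 0 has 1 non-zero in x
        t = np.array([[4.0, 1.0], [5.0, 2.0]])
        out, info = rescale_genes(t, x, return_info=True)
        np.testing.assert_allclose(out[:, 0], t[:, 0])
        assert not info["scaled"][0]

    def test_zeros_stay_zero(self):
        rng = np.random.default_rng(5)
        x = rng.random((30, 6)) * (rng.random((30, 6)) < 0.5)
        t = rng.random((30, 6)) * (rng.random((30, 6)) < 0.5)
        out = rescale_genes(t, x)
        assert np.all(out[t == 0] == 0)


class TestRestoreObserved:
    def test_restores_zeroed_observed_entry(self):
        out, mask = restore_observed(np.array([[0.0]]), np.array([[2.0]]))
        assert out[0, 0] == 2.0 and mask[0, 0]

    def test_observed_zero_stays_zero(self):
        out, mask = restore_observed(np.array([[0.0]]), np.array([[0.0]]))
        assert out[0, 0] == 0.0 and not mask[0, 0]

    def test_surviving_value_not_overwritten(self):
        out, mask = restore_observed(np.array([[1.3]]), np.array([[2.0]]))
        assert out[0, 0] == 1.3 and not mask[0, 0]


class TestPipeline:
    def test_seeded_runs_identical(self, small_sim):
        ds, _ = small_sim
        a = run_alra(ds.counts, k=3, seed=7)
        b = run_alra(ds.counts, k=3, seed=7)
        assert np.array_equal(a.imputed, b.imputed)
        assert np.array_equal(a.restored_mask, b.restored_mask)

    def test_zero_set_monotone_and_nonnegative(self, medium_sim):
        ds, _ = medium_sim
        res = run_alra(ds.counts, seed=7)
        xn = normalize(ds.counts)
        zeros_in = xn.zero_mask()
        assert np.all(res.imputed >= 0)
        # zeros(imputed) subset of zeros(input); observed values never destroyed
        assert np.all(zeros_in[res.imputed == 0])
        assert np.all(res.imputed[~zeros_in] != 0)

    def test_restore_flag_semantics(self, small_sim):
        ds, _ = small_sim
        xn = normalize(ds.counts)
        observed = ~xn.zero_mask()
        with_restore = run_alra(xn, k=3, seed=7, restore=True)
        without = run_alra(xn, k=3, seed=7, restore=False)
        assert not np.any(observed & (with_restore.imputed == 0))
        assert np.any(observed & (without.imputed == 0))

    def test_zero_preservation_on_simulated_ground_truth(self, medium_sim):
        ds, _ = medium_sim
        res = run_alra(ds.counts, seed=7)
        metrics = alra.sim_zero_metrics(ds, res.imputed)
        assert metrics.zp >= 0.95

    def test_exact_and_randomized_agree(self, small_sim):
        ds, _ = small_sim
        a = run_alra(ds.counts, k=3, seed=7, svd_method="randomized")
        b = run_alra(ds.counts, k=3, seed=7, svd_method="exact")
        assert np.array_equal(a.imputed == 0, b.imputed == 0)
        np.testing.assert_allclose(a.imputed, b.imputed, atol=1e-4)

    def test_rank_override_skips_estimation(self, small_sim):
        ds, _ = small_sim
        res = run_alra(ds.counts, k=4, seed=7)
        assert res.lowrank.k == 4
        assert res.rank_estimate is None

    def test_provenance_fields(self, small_sim):
        ds, _ = small_sim
        res = run_alra(ds.counts, k=3, seed=7)
        assert res.thresholds.tau.shape == (ds.counts.n_genes,)
        assert res.rescale_applied
        assert res.restored_mask.dtype == bool
        assert res.gene_ids == ds.counts.gene_ids


class TestEstimatorAPI:
    def test_get_set_params_and_clone(self):
        est = ALRA(k=5, alpha=2000.0, random_state=1)
        assert est.get_params()["alpha"] == 2000.0
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(quantile_p=0.01)
        assert est.quantile_p == 0.01

    def test_fitted_attributes(self, small_sim):
        ds, _ = small_sim
        est = ALRA(k=3, random_state=0).fit(ds.counts)
        assert est.rank_ == 3
        assert est.components_.shape == (3, ds.counts.n_genes)
        assert est.singular_values_.shape == (3,)
        assert est.result_.imputed.shape == ds.counts.shape

    def test_transform_consistent_with_fit_transform(self, small_sim):
        ds, _ = small_sim
        est = ALRA(k=3, random_state=0, svd_method="exact")
        fitted = est.fit_transform(ds.counts)
        projected = est.transform(ds.counts)
        np.testing.assert_allclose(projected, fitted, atol=1e-8)

    def test_transform_rejects_wrong_gene_space(self, small_sim):
        ds, _ = small_sim
        est = ALRA(k=3, random_state=0).fit(ds.counts)
        with pytest.raises(ValueError, match="genes"):
            est.transform(np.ones((5, 3)))

    def test_accepts_plain_arrays(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, (40, 25))
        counts[counts.sum(axis=1) == 0, 0] = 1
        out = ALRA(k=2, random_state=0).fit_transform(counts)
        assert out.shape == (40, 25)
        assert np.all(out >= 0)

    def test_moment_matching_after_rescale(self, small_sim):
        """Non-zero mean/sd per gene match the normalized matrix when nothing
        was clamped."""
        ds, _ = small_sim
        est = ALRA(k=3, random_state=0).fit(ds.counts)
        xn = est.normalized_.to_dense()
        t = apply_thresholds(est.lowrank_, est.thresholds_)
        resc, info = rescale_genes(t, est.normalized_, return_info=True)
        for j in np.flatnonzero(info["scaled"] & (info["n_clamped_per_gene"] == 0)):
            a = resc[:, j][resc[:, j] != 0]
            b = xn[:, j][xn[:, j] != 0]
            assert a.mean() == pytest.approx(b.mean(), abs=1e-6)
            assert a.std(ddof=1) == pytest.approx(b.std(ddof=1), abs=1e-6)


def test_normalized_input_bypasses_normalization(small_sim):
    ds, _ = small_sim
    xn = normalize(ds.counts)
    a = run_alra(xn, k=3, seed=1)
    b = run_alra(ds.counts, k=3, seed=1)
    np.testing.assert_allclose(a.imputed, b.imputed, atol=1e-12)
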