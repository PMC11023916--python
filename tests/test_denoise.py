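import numpy as np
import pytest
from scipy import stats

from offcall.denoise import (benchmark_pca_vs_loopca, choose_k,
                             fit_control_pcs, inject_artificial_cnvs,
                             recalibrate_controls, remove_pcs,
                             remove_pcs_matrix)
from conftest import make_ratio_batch


class TestFitControlPcs:
    def test_rank1_shared_noise_captured_by_first_component(self):
        rng = np.random.default_rng(0)
        pattern = rng.normal(size=500)
        loadings = rng.normal(size=12)
        R = 1.0 + np.outer(pattern, loadings) \
            + rng.normal(scale=1e-4, size=(500, 12))
        basis = fit_control_pcs(R)
        assert basis.explained_variance_ratio[0] > 0.99

    def test_basis_orthonormal(self):
        _, controls, _ = make_ratio_batch(seed=1)
        basis = fit_control_pcs(controls)
        gram = basis.components.T @ basis.components
        np.testing.assert_allclose(gram, np.eye(basis.n_components), atol=1e-8)

    def test_sample_permutation_spans_same_subspace(self):
        _, controls, rng = make_ratio_batch(seed=2)
        b1 = fit_control_pcs(controls)
        b2 = fit_control_pcs(controls[:, rng.permutation(controls.shape[1])])
        p1 = b1.components @ b1.components.T
        p2 = b2.components @ b2.components.T
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_degenerate_matrix_gives_empty_basis(self, caplog):
        basis = fit_control_pcs(np.ones((100, 5)))
        assert basis.n_components == 0
        assert "degenerate" in caplog.text

    def test_agrees_with_sklearn_pca(self):
        """Cross-check the component subspace against an independent
        PCA implementation."""
        from sklearn.decomposition import PCA
        _, controls, _ = make_ratio_batch(n_bins=300, seed=3)
        basis = fit_control_pcs(controls)
        ref = PCA(n_components=5).fit(controls.T)
        for i in range(5):
            dot = abs(np.dot(basis.components[:, i], ref.components_[i]))
            assert dot == pytest.approx(1.0, abs=1e-6)


class TestRemovePcs:
    def test_k0_identity(self):
        test, controls, _ = make_ratio_batch(seed=4)
        basis = fit_control_pcs(controls)
        np.testing.assert_array_equal(remove_pcs(test, basis, 0), test)

    def test_vector_in_span_flattens_to_center(self):
        _, controls, rng = make_ratio_batch(seed=5)
        basis = fit_control_pcs(controls)
        x = basis.center + basis.components[:, :3] @ rng.normal(size=3)
        np.testing.assert_allclose(remove_pcs(x, basis, 3), basis.center,
                                   atol=1e-10)

    def test_idempotent_and_residual_orthogonal(self):
        test, controls, _ = make_ratio_batch(seed=6)
        basis = fit_control_pcs(controls)
        d1 = remove_pcs(test, basis, 4)
        d2 = remove_pcs(d1, basis, 4)
        np.testing.assert_allclose(d1, d2, atol=1e-10)
        resid = d1 - basis.center
        assert np.abs(basis.components[:, :4].T @ resid).max() < 1e-8

    def test_negative_k_errors(self):
        _, controls, _ = make_ratio_batch(seed=7)
        with pytest.raises(ValueError):
            remove_pcs(np.ones(1000), fit_control_pcs(controls), -1)

    def test_orthogonal_cnv_amplitude_preserved(self):
        """A CNV pattern absent from the controls survives removal of
        any number of components within 1%."""
        test, controls, _ = make_ratio_batch(n_bins=2000, seed=8,
                                             noise_sd=0.0)
        basis = fit_control_pcs(controls)
        cnv = np.zeros(2000)
        cnv[100:120] = -0.5
        # project the CNV off the control subspace so it is exactly orthogonal
        cnv -= basis.components @ (basis.components.T @ cnv)
        amp0 = np.abs(cnv[100:120]).mean()
        for k in range(0, basis.n_components + 1):
            den = remove_pcs(test + cnv, basis, k) - remove_pcs(test, basis, k)
            assert np.abs(den[100:120]).mean() == pytest.approx(amp0, rel=0.01)

    def test_matrix_form_matches_vector_form(self):
        test, controls, _ = make_ratio_batch(seed=9)
        basis = fit_control_pcs(controls)
        M = remove_pcs_matrix(controls, basis, 3)
        for j in range(0, controls.shape[1], 3):
            np.testing.assert_allclose(M[:, j],
                                       remove_pcs(controls[:, j], basis, 3))


class TestInjectArtificialCnvs:
    def test_factors_half_deletion_half_duplication(self):
        ratio = np.ones(5000)
        modified, art = inject_artificial_cnvs(ratio, seed=0)
        assert art.bin_indices.size == 1000
        assert (art.factors == 0.5).sum() == 500
        assert (art.factors == 1.5).sum() == 500
        assert set(np.unique(modified[art.bin_indices])) == {0.5, 1.5}
        untouched = np.setdiff1d(np.arange(5000), art.bin_indices)
        assert (modified[untouched] == 1.0).all()

    def test_selection_without_replacement_and_reproducible(self):
        ratio = np.ones(3000)
        _, a1 = inject_artificial_cnvs(ratio, seed=42)
        _, a2 = inject_artificial_cnvs(ratio, seed=42)
        assert len(set(a1.bin_indices)) == a1.bin_indices.size
        np.testing.assert_array_equal(a1.bin_indices, a2.bin_indices)

    def test_small_bin_sets_keep_negatives(self):
        _, art = inject_artificial_cnvs(np.ones(100), seed=1)
        assert art.bin_indices.size == 50


class TestChooseK:
    def test_clean_signal_ties_break_to_zero(self):
        rng = np.random.default_rng(0)
        controls = 1.0 + rng.normal(scale=1e-3, size=(2000, 10))
        test = 1.0 + rng.normal(scale=1e-3, size=2000)
        basis = fit_control_pcs(controls)
        modified, art = inject_artificial_cnvs(test, seed=1)
        k_best, table = choose_k(modified, basis, controls, art,
                                 k_grid=range(0, 6))
        assert table["auc"].iloc[0] == pytest.approx(1.0)
        assert k_best == 0

    def test_rank1_noise_rewards_removal(self):
        rng = np.random.default_rng(1)
        pattern = rng.normal(scale=0.4, size=3000)
        loadings = rng.normal(size=10)
        controls = 1.0 + np.outer(pattern, loadings) \
            + rng.normal(scale=0.02, size=(3000, 10))
        test = 1.0 + pattern * rng.normal() \
            + rng.normal(scale=0.02, size=3000)
        basis = fit_control_pcs(controls)
        modified, art = inject_artificial_cnvs(test, seed=2)
        _, table = choose_k(modified, basis, controls, art, k_grid=[0, 1])
        assert table.loc[1, "auc"] > table.loc[0, "auc"]

    def test_auc_degrades_with_label_noise(self):
        """Corrupting an increasing share of the truth labels drags the
        measured AUC monotonically toward chance."""
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(2)
        labels = np.zeros(2000, dtype=bool)
        labels[:400] = True
        scores = np.where(labels, 5.0, 0.0) + rng.normal(size=2000)
        aucs = []
        for frac in (0.0, 0.2, 0.4, 0.8):
            noisy = labels.copy()
            flip = rng.choice(2000, size=int(frac * 2000), replace=False)
            noisy[flip] = rng.random(flip.size) < 0.2
            aucs.append(roc_auc_score(noisy, scores))
        assert all(a >= b - 1e-9 for a, b in zip(aucs, aucs[1:]))

    def test_all_bins_injected_errors(self):
        rng = np.random.default_rng(3)
        controls = 1.0 + rng.normal(scale=0.01, size=(50, 5))
        basis = fit_control_pcs(controls)
        from offcall.denoise import ArtificialCnvSet
        art = ArtificialCnvSet(bin_indices=np.arange(50),
                               factors=np.full(50, 0.5), seed=0)
        with pytest.raises(ValueError, match="AUC undefined"):
            choose_k(np.ones(50) * 0.5, basis, controls, art, k_grid=[0])


class TestLooVsPca:
    def make_deletion_batch(self, seed=0, n_bins=1000, n_controls=10):
        test, controls, _ = make_ratio_batch(
            n_bins=n_bins, n_controls=n_controls, rank=3, factor_sd=0.05,
            noise_sd=0.02, seed=seed)
        test = test.copy()
        test[200:220] *= 0.5  # 20-bin heterozygous deletion, test only
        return test, controls

    def test_loo_preserves_het_deletion_pca_erases_it(self):
        """With a 20-bin heterozygous deletion only in the test sample,
        LOO keeps the mean denoised ratio near 0.5 for k=0..5 while
        test-included PCA pulls it back toward 1."""
        for seed in range(3):
            test, controls = self.make_deletion_batch(seed=seed)
            loo = fit_control_pcs(controls)
            incl = fit_control_pcs(np.column_stack([controls, test]))
            for k in range(6):
                m = remove_pcs(test, loo, k)[200:220].mean()
                assert 0.45 <= m <= 0.60, f"LOO mean {m} at k={k}"
            assert remove_pcs(test, incl, 5)[200:220].mean() > 0.8

    def test_k0_identical_between_methods(self):
        test, controls = self.make_deletion_batch(seed=5)
        table = benchmark_pca_vs_loopca(test, controls, seed=1,
                                        k_grid=[0], n_artificial=200)
        assert table.loc[0, "auc_loo"] == pytest.approx(table.loc[0, "auc_pca"])

    def test_auc_ordering_small_batch(self):
        """LOO-PCA stays near its peak while standard PCA collapses as
        more components are removed (small-batch regime)."""
        test, controls, _ = make_ratio_batch(
            n_bins=3000, n_controls=10, rank=3, factor_sd=0.05,
            noise_sd=0.02, seed=10)
        table = benchmark_pca_vs_loopca(test, controls, seed=2,
                                        k_grid=range(0, 10))
        loo, pca = table["auc_loo"], table["auc_pca"]
        assert loo.iloc[1:].min() >= loo.max() - 0.02
        assert pca.max() - pca.iloc[-1] > 0.1


def test_recalibration_restores_control_sd_scale():
    """Removing k components shrinks the control residual SD by the
    sqrt((m-1-k)/(m-1)) degrees-of-freedom factor while the test sample
    keeps its full noise; recalibration restores the average SD scale
    (per-bin Z stays slightly heavy-tailed because each SD estimate has
    few residual degrees of freedom, but the gross inflation is gone)."""
    rng = np.random.default_rng(0)
    n_bins, m, k, sigma = 4000, 16, 10, 0.05
    controls = 1.0 + rng.normal(scale=sigma, size=(n_bins, m))
    test = 1.0 + rng.normal(scale=sigma, size=n_bins)
    basis = fit_control_pcs(controls)
    den_t = remove_pcs(test, basis, k)
    den_c = remove_pcs_matrix(controls, basis, k)
    cal = recalibrate_controls(den_c, k, m)
    # average calibrated SD recovers the generating noise level
    assert cal.std(axis=1, ddof=1).mean() == pytest.approx(sigma, rel=0.12)
    z_raw = (den_t - den_c.mean(axis=1)) / den_c.std(axis=1, ddof=1)
    z = (den_t - cal.mean(axis=1)) / cal.std(axis=1, ddof=1)
    assert np.std(z_raw) > 1.6              # uncalibrated Z grossly inflates
    assert np.std(z) < 0.75 * np.std(z_raw)  # calibration removes the bulk
    assert np.std(z) < 1.5
    # means are untouched by the rescaling
    np.testing.assert_allclose(cal.mean(axis=1), den_c.mean(axis=1),
                               atol=1e-12)
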