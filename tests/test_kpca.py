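"""Riemann kernel PCA, its baselines, and their oracle cross-checks."""

import numpy as np
import pytest
from scipy.stats import ortho_group

import riemannfc as rf
from riemannfc.kpca import (EuclideanGaussianKernelPCA, LinearPCAModel,
                            RiemannKernelPCA, _logs_from_inputs)

from conftest import random_spd


class TestKernelMatrix:
    def test_identical_inputs_give_all_ones(self):
        S = random_spd(np.random.default_rng(0), 6)
        K = rf.kernel_matrix([S, S, S], sigma=0.7)
        np.testing.assert_allclose(K, np.ones((3, 3)), atol=1e-12)

    def test_pair_at_distance_sigma_sqrt2(self):
        # d(e^c * I, I) = c * sqrt(k); choose sigma so d^2 = 2 sigma^2
        k, c = 4, 0.5
        d = c * np.sqrt(k)
        sigma = d / np.sqrt(2.0)
        K = rf.kernel_matrix([np.exp(c) * np.eye(k), np.eye(k)], sigma=sigma)
        assert K[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)
        assert K[0, 1] == pytest.approx(0.367879, abs=1e-6)

    def test_psd_unit_diagonal_on_random_subjects(self):
        rng = np.random.default_rng(4)
        mats = [rf.fc_from_timeseries(rng.standard_normal((80, 20)))
                for _ in range(50)]
        K = rf.kernel_matrix(mats, sigma=rf.default_sigma(mats))
        np.testing.assert_array_equal(np.diag(K), 1.0)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K)[0] >= -1e-8

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            rf.kernel_matrix([np.eye(2), np.eye(2)], sigma=0.0)


class TestDefaultSigma:
    def test_identical_matrices_rejected_with_guidance(self):
        S = random_spd(np.random.default_rng(1), 4)
        with pytest.raises(ValueError, match="manually"):
            rf.default_sigma([S, S, S])

    def test_single_entry_closed_form(self):
        # two 1x1 SPD inputs with logs {0, ln 2}: sigma = sample SD
        sigma = rf.default_sigma([np.array([[1.0]]), np.array([[2.0]])])
        expected = np.std([0.0, np.log(2.0)], ddof=1)
        assert sigma == pytest.approx(expected, abs=1e-12)
        assert sigma == pytest.approx(0.4901, abs=1e-4)

    def test_homogeneous_in_log_scale(self):
        rng = np.random.default_rng(2)
        mats = [random_spd(rng, 5) for _ in range(6)]
        base = rf.default_sigma(mats)
        # scaling every log-matrix by c means raising each SPD input to the
        # power c; sigma scales by |c|
        powered = []
        for S in mats:
            w, U = np.linalg.eigh(S)
            powered.append((U * w ** 3.0) @ U.T)
        assert rf.default_sigma(powered) == pytest.approx(3.0 * base,
                                                          rel=1e-10)


class TestRiemannKernelPCA:
    def test_identical_matrices_cannot_be_fitted(self):
        S = random_spd(np.random.default_rng(3), 5)
        with pytest.raises(ValueError):
            RiemannKernelPCA().fit([S] * 6)

    def test_transform_matches_fit_time_projection(self, small_cohort):
        mats, _ = small_cohort
        model = RiemannKernelPCA().fit(mats)
        scores = model.transform(mats)
        np.testing.assert_allclose(scores, model.training_scores_, atol=1e-8)

    def test_identical_new_subjects_get_identical_features(self, small_cohort):
        mats, _ = small_cohort
        model = RiemannKernelPCA().fit(mats[:15])
        out = model.transform([mats[16], mats[16]])
        np.testing.assert_array_equal(out[0], out[1])

    def test_training_order_permutation_leaves_new_features(self,
                                                            small_cohort):
        mats, _ = small_cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(15)
        a = RiemannKernelPCA(n_components=5).fit([mats[i] for i in range(15)])
        b = RiemannKernelPCA(n_components=5).fit([mats[i] for i in perm])
        fa = a.transform(mats[15:])
        fb = b.transform(mats[15:])
        # components are defined up to sign
        np.testing.assert_allclose(np.abs(fa), np.abs(fb), atol=1e-8)

    def test_rotation_invariance_of_kernel(self):
        rng = np.random.default_rng(8)
        laps = [random_spd(rng, 6) for _ in range(8)]
        Q = ortho_group.rvs(6, random_state=1)
        K1 = rf.kernel_matrix(laps, sigma=0.8)
        K2 = rf.kernel_matrix([Q @ S @ Q.T for S in laps], sigma=0.8)
        np.testing.assert_allclose(K1, K2, atol=1e-8)

    def test_score_norms_conserve_eigenvalue_trace(self, small_cohort):
        mats, _ = small_cohort
        model = RiemannKernelPCA(n_components=10).fit(mats)
        # ||score column j||^2 = lambda_j for the unit-axis normalization
        np.testing.assert_allclose(
            (model.training_scores_ ** 2).sum(axis=0),
            model.eigenvalues_, rtol=1e-8)

    def test_unit_axis_normalization_invariant(self, small_cohort):
        mats, _ = small_cohort
        model = RiemannKernelPCA(n_components=6).fit(mats)
        for j in range(model.n_components_):
            a = model.alphas_[:, j]
            assert model.eigenvalues_[j] * (a @ a) == pytest.approx(1.0,
                                                                    rel=1e-8)

    def test_excess_components_reduced_with_warning(self):
        rng = np.random.default_rng(5)
        S = random_spd(rng, 4)
        # a duplicated subject leaves the centered kernel with rank 1 < m - 1
        mats = [S, S, random_spd(rng, 4)]
        with pytest.warns(UserWarning, match="reducing"):
            model = RiemannKernelPCA(n_components=2).fit(mats)
        assert model.n_components_ == 1

    def test_dimension_mismatch_rejected(self, small_cohort):
        mats, _ = small_cohort
        model = RiemannKernelPCA().fit(mats)
        with pytest.raises(ValueError, match="mismatch"):
            model.transform([np.eye(4)])


class TestLargeSigmaLinearLimit:
    def test_euclidean_kernel_pca_matches_linear_pca(self):
        # with sigma >> data scale the centered Gaussian kernel is an affine
        # image of the Gram matrix, so scores match linear PCA per component
        rng = np.random.default_rng(30)
        mats = [rf.fc_from_timeseries(rng.standard_normal((100, 12)))
                for _ in range(30)]
        big_sigma = 1e3 * rf.default_sigma(mats, space="raw")
        kp = EuclideanGaussianKernelPCA(sigma=big_sigma,
                                        n_components=5).fit(mats)
        lp = LinearPCAModel(n_components=5).fit(mats)
        for j in range(5):
            r = np.corrcoef(kp.training_scores_[:, j],
                            lp.training_scores_[:, j])[0, 1]
            assert abs(r) > 0.999


class TestBaselines:
    def test_linear_pca_full_rank_reconstruction_lossless(self, small_cohort):
        mats, _ = small_cohort
        model = LinearPCAModel(n_components=len(mats) - 1).fit(mats)
        X = model._embed(mats)
        back = model.inverse_transform(model.training_scores_)
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_linear_pca_matches_covariance_eigendecomposition(self,
                                                              small_cohort):
        # independent oracle: eigendecompose the sample covariance directly
        mats, _ = small_cohort
        model = LinearPCAModel(n_components=4).fit(mats)
        X = model._embed(mats)
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
        w, V = w[::-1], V[:, ::-1]
        oracle = Xc @ V[:, :4]
        for j in range(4):
            r = np.corrcoef(model.training_scores_[:, j], oracle[:, j])[0, 1]
            assert abs(r) > 1 - 1e-10

    def test_gaussian_baseline_with_riemann_embedding_equals_riemann(
            self, small_cohort):
        # swapping the log-Euclidean embedding into the Euclidean-Gaussian
        # code path must reproduce the Riemann model exactly
        mats, _ = small_cohort

        class SwappedKPCA(EuclideanGaussianKernelPCA):
            def _embed(self, inputs, training=False):
                logs = _logs_from_inputs(inputs, 1.0, "abs")
                return logs.reshape(len(logs), -1)

        riemann = RiemannKernelPCA(n_components=5).fit(mats)
        swapped = SwappedKPCA(n_components=5).fit(mats)
        assert swapped.sigma_ == riemann.sigma_
        np.testing.assert_allclose(np.abs(swapped.training_scores_),
                                   np.abs(riemann.training_scores_),
                                   atol=1e-10)


def test_model_save_load_round_trip(tmp_path, small_cohort):
    mats, _ = small_cohort
    model = RiemannKernelPCA(n_components=5).fit(mats[:15])
    path = rf.save_model(tmp_path / "model.npz", model)
    back = rf.load_model(path)
    np.testing.assert_allclose(back.transform(mats[15:]),
                               model.transform(mats[15:]), atol=1e-12)
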