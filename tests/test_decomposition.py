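import numpy as np
import pytest
from sklearn.decomposition import PCA, KernelPCA
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics.pairwise import pairwise_kernels

from conftest import standardized
from covaritools.decomposition import (
    KernelPCovC,
    KernelPCovR,
    PCovC,
    PCovR,
    reconstruction_losses,
)
from covaritools.fixtures import (
    make_labeled_blobs,
    make_lowrank_regression,
    make_rings,
)
from covaritools.preprocessing import FeatureScaler, KernelNormalizer


def sign_align(T, ref):
    """Flip columns of T to match the sign pattern of ref."""
    s = np.sign(np.sum(T * ref, axis=0))
    s[s == 0] = 1.0
    return T * s


class TestPCovR:
    def test_alpha_one_is_pca(self, rng):
        X = standardized(rng.standard_normal((60, 10)))
        Y = standardized(rng.standard_normal((60, 2)), "per_column")
        T = PCovR(mixing=1.0, n_components=3).fit(X, Y).T_
        T_pca = PCA(n_components=3).fit_transform(X)
        np.testing.assert_allclose(sign_align(T, T_pca), T_pca, atol=1e-8)

    def test_alpha_zero_matches_base_regressor(self, regression_problem):
        X, Y = regression_problem
        model = PCovR(mixing=0.0, n_components=2).fit(X, Y)
        base = Ridge(alpha=1e-8, fit_intercept=False).fit(X, Y)
        np.testing.assert_allclose(model.predict(X), base.predict(X), atol=1e-8)

    def test_planted_model_out_of_sample_recovery(self):
        # rank-2 planted signal: two covariates can represent it exactly
        bundle = make_lowrank_regression(n=200, p=8, r=2, q=1, noise_sd=0.0, seed=5)
        tr, te = np.arange(0, 150), np.arange(150, 200)
        sx = FeatureScaler().fit(bundle["X"][tr])
        sy = FeatureScaler(mode="per_column").fit(bundle["Y"][tr])
        X, Y = sx.transform(bundle["X"]), sy.transform(bundle["Y"])
        model = PCovR(mixing=0.5, n_components=2).fit(X[tr], Y[tr])
        pred = model.predict(X[te])
        r2 = 1 - np.sum((Y[te] - pred) ** 2) / np.sum((Y[te] - Y[te].mean()) ** 2)
        assert r2 > 0.999

    def test_transform_is_consistent_and_deterministic(self, regression_problem):
        X, Y = regression_problem
        model = PCovR(mixing=0.4, n_components=3).fit(X, Y)
        np.testing.assert_allclose(model.transform(X), model.T_, atol=1e-8)
        doubled = np.vstack([X[:1], X[:1]])
        T2 = model.transform(doubled)
        np.testing.assert_array_equal(T2[0], T2[1])

    @pytest.mark.parametrize("seed", range(20))
    def test_route_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n, p = (30, 12) if seed % 2 else (40, 6)  # covers n > p and n < p
        X = standardized(rng.standard_normal((n, p)))
        Y = standardized(
            X @ rng.standard_normal((p, 2)) + 0.2 * rng.standard_normal((n, 2)),
            "per_column",
        )
        ms = PCovR(mixing=0.5, n_components=3, route="sample_space").fit(X, Y)
        mf = PCovR(mixing=0.5, n_components=3, route="feature_space").fit(X, Y)
        np.testing.assert_allclose(ms.eigenvalues_, mf.eigenvalues_, atol=1e-6)
        np.testing.assert_allclose(sign_align(mf.T_, ms.T_), ms.T_, atol=1e-6)

    def test_latent_covariance_is_diagonal(self, regression_problem):
        X, Y = regression_problem
        for a in (0.0, 0.3, 1.0):
            model = PCovR(mixing=a, n_components=2).fit(X, Y)
            G = model.T_.T @ model.T_
            np.testing.assert_allclose(G, np.diag(model.eigenvalues_), atol=1e-8)

    def test_full_rank_alpha_one_prediction_is_ols(self, rng):
        X = standardized(rng.standard_normal((50, 5)))
        Y = standardized(
            X @ rng.standard_normal((5, 1)) + 0.1 * rng.standard_normal((50, 1)),
            "per_column",
        )
        model = PCovR(mixing=1.0, n_components=5).fit(X, Y)
        T = PCA(n_components=5).fit_transform(X)
        W, *_ = np.linalg.lstsq(T, Y, rcond=None)
        np.testing.assert_allclose(model.predict(X), T @ W, atol=1e-6)

    def test_inverse_transform(self, rng):
        X = standardized(rng.standard_normal((50, 6)))
        Y = standardized(rng.standard_normal((50, 1)), "per_column")
        full = PCovR(mixing=1.0, n_components=6).fit(X, Y)
        np.testing.assert_allclose(
            full.inverse_transform(full.T_), X, atol=1e-6
        )
        m = 2
        part = PCovR(mixing=1.0, n_components=m).fit(X, Y)
        resid = np.linalg.norm(X - part.inverse_transform(part.transform(X)))
        s = np.linalg.svd(X, compute_uv=False)
        np.testing.assert_allclose(resid, np.sqrt(np.sum(s[m:] ** 2)), atol=1e-6)
        assert np.abs(part.inverse_transform(np.zeros((3, m)))).max() == 0

    def test_eigenvalue_continuity_in_mixing(self, regression_problem):
        X, Y = regression_problem
        delta = 1e-6
        a = 0.5
        l0 = PCovR(mixing=a, n_components=2).fit(X, Y).eigenvalues_
        l1 = PCovR(mixing=a + delta, n_components=2).fit(X, Y).eigenvalues_
        # Weyl: eigenvalues move at most by the spectral norm of the change
        bound = delta * (
            np.linalg.norm(X @ X.T, 2) + np.linalg.norm(Y @ Y.T, 2) * 2
        )
        assert np.abs(l1 - l0).max() <= bound + 1e-9

    def test_input_validation(self, rng):
        X = standardized(rng.standard_normal((30, 4)))
        Y = standardized(rng.standard_normal((30, 1)), "per_column")
        with pytest.raises(ValueError, match="mixing"):
            PCovR(mixing=1.5)
        with pytest.raises(ValueError, match="attainable rank"):
            PCovR(mixing=1.0, n_components=10).fit(X, Y)
        with pytest.raises(ValueError, match="centered"):
            PCovR().fit(X + 5.0, Y)
        with pytest.raises(ValueError, match="zero-variance"):
            PCovR().fit(X, np.zeros((30, 1)))


class TestKernelPCovR:
    def test_linear_kernel_matches_linear_pcovr(self, regression_problem):
        X, Y = regression_problem
        lin = PCovR(mixing=0.5, n_components=3, route="sample_space").fit(X, Y)
        ker = KernelPCovR(mixing=0.5, n_components=3, kernel="linear").fit(X, Y)
        np.testing.assert_allclose(sign_align(ker.T_, lin.T_), lin.T_, atol=1e-6)

    def test_alpha_one_is_kernel_pca(self, regression_problem):
        X, Y = regression_problem
        model = KernelPCovR(
            mixing=1.0, n_components=3, kernel="rbf", kernel_params={"gamma": 0.5}
        ).fit(X, Y)
        K = pairwise_kernels(X, metric="rbf", gamma=0.5)
        Kc = KernelNormalizer(trace_norm=True).fit_transform(K)
        T_ref = KernelPCA(n_components=3, kernel="precomputed").fit_transform(Kc)
        np.testing.assert_allclose(sign_align(model.T_, T_ref), T_ref, atol=1e-6)

    def test_alpha_zero_is_kernel_ridge(self, regression_problem):
        X, Y = regression_problem
        model = KernelPCovR(
            mixing=0.0, n_components=2, kernel="rbf", kernel_params={"gamma": 0.5}
        ).fit(X, Y)
        K = pairwise_kernels(X, metric="rbf", gamma=0.5)
        Kc = KernelNormalizer(trace_norm=True).fit_transform(K)
        ref = KernelRidge(alpha=1e-8, kernel="precomputed").fit(Kc, Y)
        np.testing.assert_allclose(model.predict(X), ref.predict(Kc), atol=1e-6)

    def test_out_of_sample_transform_consistency(self, regression_problem):
        X, Y = regression_problem
        model = KernelPCovR(
            mixing=0.5, n_components=2, kernel="rbf", kernel_params={"gamma": 1.0}
        ).fit(X, Y)
        np.testing.assert_allclose(model.transform(X), model.T_, atol=1e-8)

    def test_precomputed_kernel_shape_errors(self, regression_problem):
        X, Y = regression_problem
        with pytest.raises(ValueError, match="square"):
            KernelPCovR(kernel="precomputed").fit(X, Y)


class TestPCovC:
    def test_alpha_one_is_pca(self):
        bundle = make_labeled_blobs(n=200, n_classes=2, separation=6.0, seed=1)
        X = standardized(bundle["X"])
        y = bundle["labels"]
        T = PCovC(mixing=1.0, n_components=2).fit(X, y).T_
        T_pca = PCA(n_components=2).fit_transform(X)
        np.testing.assert_allclose(sign_align(T, T_pca), T_pca, atol=1e-8)

    def test_separable_blobs_reach_perfect_accuracy(self):
        bundle = make_labeled_blobs(n=400, n_classes=2, separation=6.0, seed=2)
        X = standardized(bundle["X"])
        y = bundle["labels"]
        # separability check: an (effectively) unregularized logistic, so
        # shrinkage cannot concede a borderline point
        clf = LogisticRegression(C=1e6, fit_intercept=False)
        model = PCovC(mixing=0.5, n_components=2, classifier=clf).fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0
        assert model.decision_function(X).shape == (400, 1)
        assert set(model.predict(X)) <= set(y)

    def test_supervision_beats_pca_on_three_blobs(self):
        bundle = make_labeled_blobs(n=300, n_classes=3, separation=3.0, p=5, seed=3,
                                    nuisance_scale=2.0)
        y = bundle["labels"]
        tr, te = np.arange(0, 225), np.arange(225, 300)
        X = FeatureScaler().fit(bundle["X"][tr]).transform(bundle["X"])
        model = PCovC(mixing=0.5, n_components=2).fit(X[tr], y[tr])
        acc_pcovc = (model.predict(X[te]) == y[te]).mean()
        pca = PCA(n_components=2).fit(X[tr])
        clf = LogisticRegression(fit_intercept=False).fit(pca.transform(X[tr]), y[tr])
        acc_pca = (clf.predict(pca.transform(X[te])) == y[te]).mean()
        assert acc_pcovc >= acc_pca

    def test_classifier_families_agree_at_alpha_one_and_differ_at_half(self):
        bundle = make_labeled_blobs(n=150, n_classes=2, separation=4.0, seed=4)
        X = standardized(bundle["X"])
        y = bundle["labels"]
        families = ["logistic", "ridge", "svm", "perceptron"]
        T1 = [
            PCovC(mixing=1.0, n_components=2, classifier=f).fit(X, y).T_
            for f in families
        ]
        for T in T1[1:]:
            np.testing.assert_allclose(sign_align(T, T1[0]), T1[0], atol=1e-8)
        T5 = [
            PCovC(mixing=0.5, n_components=2, classifier=f).fit(X, y).T_
            for f in families
        ]
        diffs = [
            np.abs(sign_align(T5[i], T5[j]) - T5[j]).max()
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        assert max(diffs) > 1e-6

    def test_input_validation(self, rng):
        X = standardized(rng.standard_normal((30, 3)))
        with pytest.raises(ValueError, match="single class"):
            PCovC(n_components=1).fit(X, np.zeros(30))
        with pytest.raises(ValueError, match="classifier family"):
            PCovC(classifier="forest").fit(X, np.arange(30) % 2)


class TestKernelPCovC:
    def test_linear_kernel_matches_linear_pcovc(self):
        bundle = make_labeled_blobs(n=150, n_classes=2, separation=4.0, seed=5)
        X = standardized(bundle["X"])
        y = bundle["labels"]
        lin = PCovC(mixing=1.0, n_components=2, route="sample_space").fit(X, y)
        ker = KernelPCovC(mixing=1.0, n_components=2, kernel="linear").fit(X, y)
        np.testing.assert_allclose(sign_align(ker.T_, lin.T_), lin.T_, atol=1e-6)

    def test_rings_need_the_kernel(self):
        bundle = make_rings(n=400, radii=(1.0, 3.0), noise_sd=0.1, seed=6)
        X = standardized(bundle["X"])
        y = bundle["labels"]
        ker = KernelPCovC(
            mixing=0.5, n_components=2, kernel="rbf", kernel_params={"gamma": 2.0}
        ).fit(X, y)
        lin = PCovC(mixing=0.5, n_components=2).fit(X, y)
        assert (ker.predict(X) == y).mean() == 1.0
        assert (lin.predict(X) == y).mean() < 0.75


class TestReconstructionLosses:
    def test_full_rank_pca_has_zero_reconstruction_loss(self, rng):
        X = standardized(rng.standard_normal((40, 5)))
        Y = standardized(rng.standard_normal((40, 1)), "per_column")
        model = PCovR(mixing=1.0, n_components=5).fit(X, Y)
        lX, _ = reconstruction_losses(model, X, Y)
        assert lX <= 1e-10

    def test_reconstruction_loss_decreases_with_components(self, regression_problem):
        X, Y = regression_problem
        losses = [
            reconstruction_losses(
                PCovR(mixing=1.0, n_components=m).fit(X, Y), X, Y
            )[0]
            for m in range(1, 7)
        ]
        assert np.all(np.diff(losses) <= 1e-12)

    def test_regression_loss_favors_supervised_mixing(self):
        bundle = make_lowrank_regression(n=150, p=8, r=8, q=1, noise_sd=0.05, seed=7)
        X = standardized(bundle["X"])
        Y = standardized(bundle["Y"], "per_column")
        lY = {
            a: reconstruction_losses(
                PCovR(mixing=a, n_components=2).fit(X, Y), X, Y
            )[1]
            for a in (0.001, 0.999)
        }
        assert lY[0.001] <= lY[0.999]
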