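"""Principal covariates regression and classification, linear and kernelized.

PCA finds the latent space that best preserves feature variance; ridge
regression finds the direction that best predicts a target.  Principal
covariates regression (PCovR) interpolates between the two by
eigendecomposing a modified Gram (or covariance) matrix

    Gt = alpha * X X^T + (1 - alpha) * Yhat Yhat^T

where ``Yhat`` are the *predicted* targets of a linear regressor and the
mixing parameter ``alpha`` in [0, 1] weights feature reconstruction
(alpha=1: PCA) against regression (alpha=0: the regressor's prediction
space).  The latent projection is ``T = U_m Lambda_m^{1/2}`` from the top-m
eigenpairs, so ``T^T T`` is diagonal.  An equivalent feature-space route
eigendecomposes the modified covariance

    Ct = alpha * C + (1 - alpha) * C^{-1/2} X^T Yhat Yhat^T X C^{-1/2}

which yields the same eigenvalues and (up to sign) the same T whenever
``Yhat`` lies in the column space of X; the smaller of the two eigenproblems
is chosen automatically.

The kernel variant (KPCovR) replaces ``X X^T`` with a centered, trace
normalized kernel and the regressor with kernel ridge.  The classification
variants (PCovC / KPCovC) replace ``Yhat`` with the decision-function values
``Z`` of a linear classifier — the class-likelihood proxy ``Z Z^T`` plays
the role of ``Yhat Yhat^T`` — and refit a fresh classifier of the same
family in the latent space to provide ``predict`` and ``decision_function``.

All estimators expect pre-standardised inputs: X centered (globally scaled
recommended) and, for regression, Y column-centered.  This keeps the two
terms of the mixture on comparable scales so that ``alpha`` is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh
from sklearn.base import clone
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LogisticRegression, Perceptron, Ridge, RidgeClassifier
from sklearn.metrics.pairwise import pairwise_kernels
from sklearn.svm import LinearSVC

from .preprocessing import KernelNormalizer

__all__ = [
    "PCovR",
    "KernelPCovR",
    "PCovC",
    "KernelPCovC",
    "reconstruction_losses",
]

_CENTER_TOL = 1e-8
_EIG_RTOL = 1e-12

CLASSIFIER_FAMILIES = ("logistic", "ridge", "svm", "perceptron")


def _check_centered(M, name):
    mu = np.abs(np.asarray(M).mean(axis=0)).max()
    if mu > _CENTER_TOL:
        raise ValueError(
            f"{name} must be column-centered (max |column mean| = {mu:.2e}); "
            "standardize inputs before fitting"
        )


def _eigh_desc(M):
    w, V = eigh((M + M.T) / 2)
    order = np.argsort(w, kind="stable")[::-1]
    return w[order], V[:, order]


def _top_m(w, V, m, what):
    cutoff = _EIG_RTOL * max(w[0], 0.0)
    avail = int(np.sum(w > cutoff))
    if m > avail:
        raise ValueError(
            f"n_components={m} exceeds the attainable rank {avail} of the {what}"
        )
    return w[:m], V[:, :m]


def _pinv_sqrt(C):
    """Pseudo-inverse square root of a PSD matrix with relative cutoff."""
    w, V = _eigh_desc(C)
    keep = w > _EIG_RTOL * max(w[0], 0.0)
    d = np.zeros_like(w)
    d[keep] = 1.0 / np.sqrt(w[keep])
    return (V * d) @ V.T


def _fix_signs(P, T):
    """Flip latent columns so each projector column's largest loading is > 0."""
    for j in range(P.shape[1]):
        i = int(np.argmax(np.abs(P[:, j])))
        if P[i, j] < 0:
            P[:, j] *= -1
            T[:, j] *= -1
    return P, T


def _as_targets(Y):
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y


def _make_classifier(spec):
    """Instantiate one of the supported linear classifier families.

    Intercepts are disabled: inputs are centered and an intercept-free
    classifier makes Z == X @ coef.T exact, which the eigendecomposition
    routes rely on.
    """
    if hasattr(spec, "fit"):
        return clone(spec)
    if spec == "logistic":
        return LogisticRegression(fit_intercept=False)
    if spec == "ridge":
        return RidgeClassifier(fit_intercept=False)
    if spec == "svm":
        return LinearSVC(fit_intercept=False, random_state=0)
    if spec == "perceptron":
        return Perceptron(fit_intercept=False, random_state=0)
    raise ValueError(
        f"unknown classifier family {spec!r}; choose from {CLASSIFIER_FAMILIES}"
    )


def _decision_values(clf, X):
    Z = clf.decision_function(X)
    if Z.ndim == 1:
        Z = Z[:, None]
    return Z


class _LinearCovBase:
    """Shared eigendecomposition machinery for linear PCovR / PCovC."""

    def __init__(self, mixing=0.5, n_components=2, route="auto"):
        if not 0.0 <= mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")
        if route not in ("auto", "sample_space", "feature_space"):
            raise ValueError(f"unknown route {route!r}")
        self.mixing = mixing
        self.n_components = int(n_components)
        self.route = route

    def _decompose(self, X, Yhat, P_XY):
        """Build T and the projectors from X and the supervised proxy Yhat."""
        a = self.mixing
        n, p = X.shape
        route = self.route
        if route == "auto":
            route = "feature_space" if p < n else "sample_space"
        if route == "sample_space":
            Gt = a * (X @ X.T) + (1 - a) * (Yhat @ Yhat.T)
            w, U = _eigh_desc(Gt)
            lam, U_m = _top_m(w, U, self.n_components, "modified Gram matrix")
            T = U_m * np.sqrt(lam)
            P_XT = (a * X.T + (1 - a) * (P_XY @ Yhat.T)) @ (U_m / np.sqrt(lam))
        else:
            C = X.T @ X
            Cinv_sqrt = _pinv_sqrt(C)
            B = Cinv_sqrt @ (X.T @ Yhat)
            Ct = a * C + (1 - a) * (B @ B.T)
            w, V = _eigh_desc(Ct)
            lam, V_m = _top_m(w, V, self.n_components, "modified covariance matrix")
            P_XT = (Cinv_sqrt @ V_m) * np.sqrt(lam)
            T = X @ P_XT
        P_XT, T = _fix_signs(P_XT, T)
        self.route_ = route
        self.eigenvalues_ = lam
        self.P_XT_ = P_XT
        self.T_ = T
        self.P_TX_ = (T.T @ X) / lam[:, None]
        self._p = p

    def transform(self, X):
        if getattr(self, "P_XT_", None) is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self._p:
            raise ValueError(
                f"X has {X.shape[1]} columns, model was fitted with {self._p}"
            )
        return X @ self.P_XT_

    def inverse_transform(self, T):
        if getattr(self, "P_TX_", None) is None:
            raise RuntimeError("model is not fitted")
        T = np.asarray(T, dtype=float)
        if T.ndim == 1:
            T = T[None, :]
        if T.shape[1] != self.P_TX_.shape[0]:
            raise ValueError(
                f"T has {T.shape[1]} columns, model has "
                f"{self.P_TX_.shape[0]} components"
            )
        return T @ self.P_TX_


class PCovR(_LinearCovBase):
    """Linear principal covariates regression.

    Parameters
    ----------
    mixing:
        alpha in [0, 1]; 1 recovers PCA, 0 the regressor's prediction space.
    n_components:
        Latent dimensionality m; must not exceed the rank of the modified
        matrix.
    regressor:
        A linear scikit-learn regressor used to form ``Yhat`` (must expose
        ``coef_`` after fitting).  Default: ``Ridge(alpha=1e-8)`` without
        intercept — essentially unregularized least squares on the already
        standardized inputs.
    route:
        ``"auto"`` picks the smaller eigenproblem; ``"sample_space"`` /
        ``"feature_space"`` force one side (they agree up to column signs).
    """

    def __init__(self, mixing=0.5, n_components=2, regressor=None, route="auto"):
        super().__init__(mixing, n_components, route)
        self.regressor = regressor

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = _as_targets(Y)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        _check_centered(X, "X")
        _check_centered(Y, "Y")
        if np.any(Y.var(axis=0) < 1e-16):
            raise ValueError("Y has a zero-variance column; standardize targets")
        reg = Ridge(alpha=1e-8, fit_intercept=False) if self.regressor is None \
            else clone(self.regressor)
        reg.fit(X, Y)
        P_XY = np.atleast_2d(reg.coef_)
        if P_XY.shape == (Y.shape[1], X.shape[1]):
            P_XY = P_XY.T
        Yhat = X @ P_XY
        self.regressor_ = reg
        self.P_XY_ = P_XY
        self._decompose(X, Yhat, P_XY)
        self.P_TY_ = (self.T_.T @ Y) / self.eigenvalues_[:, None]
        return self

    def predict(self, X):
        return self.transform(X) @ self.P_TY_


class PCovC(_LinearCovBase):
    """Linear principal covariates classification.

    The supervised proxy is the decision-function matrix Z of a linear
    classifier (one column for binary problems, one per class otherwise);
    ``Z Z^T`` replaces ``Yhat Yhat^T`` in the modified Gram matrix.  A fresh
    classifier of the same family is refit on the latent coordinates and
    provides ``predict`` / ``decision_function``.
    """

    def __init__(self, mixing=0.5, n_components=2, classifier="logistic",
                 route="auto"):
        super().__init__(mixing, n_components, route)
        self.classifier = classifier

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        _check_centered(X, "X")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("y contains a single class")
        clf = _make_classifier(self.classifier)
        clf.fit(X, y)
        P_XZ = np.atleast_2d(clf.coef_).T
        Z = X @ P_XZ
        self.feature_classifier_ = clf
        self.P_XZ_ = P_XZ
        self._decompose(X, Z, P_XZ)
        latent = _make_classifier(self.classifier)
        latent.fit(self.T_, y)
        self.latent_classifier_ = latent
        return self

    def predict(self, X):
        return self.latent_classifier_.predict(self.transform(X))

    def decision_function(self, X):
        return _decision_values(self.latent_classifier_, self.transform(X))


class _KernelCovBase:
    """Shared kernel handling for KPCovR / KPCovC."""

    def __init__(self, mixing=0.5, n_components=2, kernel="linear",
                 kernel_params=None):
        if not 0.0 <= mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")
        self.mixing = mixing
        self.n_components = int(n_components)
        self.kernel = kernel
        self.kernel_params = dict(kernel_params or {})

    def _compute_kernel(self, A, B=None):
        if self.kernel == "precomputed":
            return np.asarray(A, dtype=float)
        return pairwise_kernels(A, B, metric=self.kernel, **self.kernel_params)

    def _prepare_kernel(self, X):
        if self.kernel == "precomputed":
            K = np.asarray(X, dtype=float)
            if K.shape[0] != K.shape[1]:
                raise ValueError(f"precomputed kernel must be square, got {K.shape}")
            self.X_fit_ = None
        else:
            self.X_fit_ = np.asarray(X, dtype=float)
            K = self._compute_kernel(self.X_fit_)
        self._normalizer = KernelNormalizer(trace_norm=True).fit(K)
        K_c = self._normalizer.transform(K)
        w = np.linalg.eigvalsh((K_c + K_c.T) / 2)
        if w[0] < -1e-10 * max(1.0, w[-1]):
            raise ValueError(
                f"kernel is indefinite after centering (min eigenvalue {w[0]:.2e})"
            )
        self._n = K.shape[0]
        return K_c

    def _decompose_kernel(self, K_c, proxy, dual_weights):
        a = self.mixing
        Kt = a * K_c + (1 - a) * (proxy @ proxy.T)
        w, U = _eigh_desc(Kt)
        lam, U_m = _top_m(w, U, self.n_components, "modified kernel matrix")
        T = U_m * np.sqrt(lam)
        P_KT = (a * np.eye(self._n) + (1 - a) * (dual_weights @ proxy.T)) \
            @ (U_m / np.sqrt(lam))
        P_KT, T = _fix_signs(P_KT, T)
        self.eigenvalues_ = lam
        self.P_KT_ = P_KT
        self.T_ = T

    def _cross_centered(self, X):
        if getattr(self, "P_KT_", None) is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if self.kernel == "precomputed":
            if X.ndim != 2 or X.shape[1] != self._n:
                raise ValueError(
                    f"precomputed cross kernel must have {self._n} columns"
                )
            K = X
        else:
            if X.ndim == 1:
                X = X[None, :]
            K = self._compute_kernel(X, self.X_fit_)
        return self._normalizer.transform(K)

    def transform(self, X):
        return self._cross_centered(X) @ self.P_KT_


class KernelPCovR(_KernelCovBase):
    """Kernel principal covariates regression.

    ``alpha=1`` recovers kernel PCA of the centered, trace-normalized
    kernel; ``alpha=0`` recovers kernel ridge regression.  ``X`` may be a
    feature matrix (the kernel is built internally) or a precomputed square
    kernel with ``kernel="precomputed"``.
    """

    def __init__(self, mixing=0.5, n_components=2, kernel="linear",
                 kernel_params=None, regressor=None):
        super().__init__(mixing, n_components, kernel, kernel_params)
        self.regressor = regressor

    def fit(self, X, Y):
        Y = _as_targets(Y)
        _check_centered(Y, "Y")
        K_c = self._prepare_kernel(X)
        if K_c.shape[0] != Y.shape[0]:
            raise ValueError("kernel and Y row counts differ")
        reg = KernelRidge(alpha=1e-8, kernel="precomputed") if self.regressor is None \
            else clone(self.regressor)
        reg.fit(K_c, Y)
        W = np.asarray(reg.dual_coef_, dtype=float)
        if W.ndim == 1:
            W = W[:, None]
        Yhat = K_c @ W
        self.dual_weights_ = W
        self._decompose_kernel(K_c, Yhat, W)
        self.P_TY_ = (self.T_.T @ Y) / self.eigenvalues_[:, None]
        if self.X_fit_ is not None:
            self.P_TX_ = (self.T_.T @ self.X_fit_) / self.eigenvalues_[:, None]
        return self

    def predict(self, X):
        return self.transform(X) @ self.P_TY_

    def inverse_transform(self, T):
        if getattr(self, "P_TX_", None) is None:
            raise RuntimeError("linear reconstruction requires fitting on features")
        return np.asarray(T, dtype=float) @ self.P_TX_


class KernelPCovC(_KernelCovBase):
    """Kernel principal covariates classification.

    The linear classifier is fit on the centered kernel rows, its decision
    values supply ``Z Z^T``, and a fresh classifier of the same family is
    refit on the latent coordinates.
    """

    def __init__(self, mixing=0.5, n_components=2, kernel="linear",
                 kernel_params=None, classifier="logistic"):
        super().__init__(mixing, n_components, kernel, kernel_params)
        self.classifier = classifier

    def fit(self, X, y):
        y = np.asarray(y)
        K_c = self._prepare_kernel(X)
        if K_c.shape[0] != y.shape[0]:
            raise ValueError("kernel and y row counts differ")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("y contains a single class")
        clf = _make_classifier(self.classifier)
        clf.fit(K_c, y)
        Wz = np.atleast_2d(clf.coef_).T
        Z = K_c @ Wz
        self.kernel_classifier_ = clf
        self._decompose_kernel(K_c, Z, Wz)
        latent = _make_classifier(self.classifier)
        latent.fit(self.T_, y)
        self.latent_classifier_ = latent
        return self

    def predict(self, X):
        return self.latent_classifier_.predict(self.transform(X))

    def decision_function(self, X):
        return _decision_values(self.latent_classifier_, self.transform(X))


def reconstruction_losses(model, X, Y):
    """Normalized latent-space losses ``(lX, lY)`` of a fitted model.

    ``lX = ||X - Xhat||_F^2 / ||X||_F^2`` where ``Xhat`` is the linear
    reconstruction from the latent space, and ``lY`` is the analogous
    relative error of the predicted targets.  Both are unitless.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_targets(Y)
    nx, ny = np.linalg.norm(X) ** 2, np.linalg.norm(Y) ** 2
    if nx == 0 or ny == 0:
        raise ValueError("X and Y must be non-zero to normalize the losses")
    Xhat = model.inverse_transform(model.transform(X))
    Yhat = model.predict(X)
    if Yhat.ndim == 1:
        Yhat = Yhat[:, None]
    lX = float(np.linalg.norm(X - Xhat) ** 2 / nx)
    lY = float(np.linalg.norm(Y - Yhat) ** 2 / ny)
    return lX, lY
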