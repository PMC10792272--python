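"""Standardisation of features, targets and kernel matrices.

The latent-space methods in this package mix an unsupervised term (feature
variance) with a supervised term (regression or classification quality).
That mixture is only meaningful when both terms live on a comparable scale,
so every estimator here expects inputs that have been centered and scaled.
Two scaling conventions are provided:

``per_column``
    Classic z-scoring: each column ends up with mean 0 and variance 1.
``global``
    Columns are centered individually but share a single scale factor such
    that the *sum* of column variances is 1.  This preserves the relative
    variance structure between columns, which matters when columns are
    components of one physical descriptor rather than unrelated covariates.

Kernel matrices are centered in feature space (the implicit map is centered)
via the usual double-centering identity, delegated to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from sklearn.preprocessing import KernelCenterer as _SklearnKernelCenterer

__all__ = [
    "ScalerMode",
    "FeatureScaler",
    "scale_fit_transform",
    "KernelNormalizer",
    "center_kernel",
]


class ScalerMode(str, Enum):
    per_column = "per_column"
    global_ = "global"


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got ndim={X.ndim}")
    return X


@dataclass
class FeatureScaler:
    """Column-centering scaler with per-column or global variance scaling.

    Parameters
    ----------
    mode:
        ``"per_column"`` scales every column to unit variance;
        ``"global"`` applies one common factor so the column variances sum
        to 1.  Constant columns are an error in per-column mode (their scale
        is undefined) and are tolerated in global mode.
    ddof:
        Delta degrees of freedom of the variance estimator.  The default 0
        makes "total variance 1" exact: ``||transform(X)||_F^2 == n`` in
        global mode.
    """

    mode: str = "global"
    ddof: int = 0
    column_means_: np.ndarray = field(default=None, repr=False)
    scales_: np.ndarray = field(default=None, repr=False)

    def fit(self, X) -> "FeatureScaler":
        X = _as_2d(X)
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 rows to fit a scaler")
        mode = ScalerMode(self.mode)
        self.column_means_ = X.mean(axis=0)
        var = X.var(axis=0, ddof=self.ddof)
        if mode is ScalerMode.per_column:
            bad = np.flatnonzero(var <= 0)
            if bad.size:
                raise ValueError(
                    f"constant column(s) {bad.tolist()} cannot be scaled in "
                    "per_column mode"
                )
            self.scales_ = np.sqrt(var)
        else:
            total = var.sum()
            if total <= 0:
                raise ValueError("matrix has zero total variance")
            self.scales_ = np.full(p, np.sqrt(total))
        return self

    def _check(self, X) -> np.ndarray:
        if self.column_means_ is None:
            raise RuntimeError("scaler is not fitted")
        X = _as_2d(X)
        if X.shape[1] != self.column_means_.shape[0]:
            raise ValueError(
                f"column count {X.shape[1]} does not match the "
                f"{self.column_means_.shape[0]} columns seen at fit time"
            )
        return X

    def transform(self, X) -> np.ndarray:
        X = self._check(X)
        return (X - self.column_means_) / self.scales_

    def inverse_transform(self, X) -> np.ndarray:
        X = self._check(X)
        return X * self.scales_ + self.column_means_

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)


def scale_fit_transform(X, mode: str = "global", ddof: int = 0):
    """Fit a :class:`FeatureScaler` and return ``(scaler, transformed_X)``."""
    scaler = FeatureScaler(mode=mode, ddof=ddof)
    Xt = scaler.fit_transform(X)
    return scaler, Xt


class KernelNormalizer:
    """Center (and optionally trace-normalize) kernel matrices.

    Centering uses the training-kernel statistics, so out-of-sample cross
    kernels are centered consistently with the training block.  With
    ``trace_norm=True`` the centered training kernel is rescaled so that
    ``trace(Kc)/n == 1``, mirroring the "total variance 1" convention of the
    global feature scaler; the same factor is applied to cross kernels.
    """

    def __init__(self, trace_norm: bool = False):
        self.trace_norm = trace_norm
        self._centerer = None
        self.scale_ = 1.0

    def fit(self, K_train) -> "KernelNormalizer":
        K = np.asarray(K_train, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError(f"training kernel must be square, got {K.shape}")
        self._centerer = _SklearnKernelCenterer().fit(K)
        self.n_train_ = K.shape[0]
        if self.trace_norm:
            Kc = self._centerer.transform(K)
            tr = np.trace(Kc)
            if tr <= 0:
                raise ValueError("centered kernel has non-positive trace")
            self.scale_ = self.n_train_ / tr
        return self

    def transform(self, K) -> np.ndarray:
        if self._centerer is None:
            raise RuntimeError("kernel normalizer is not fitted")
        K = np.asarray(K, dtype=float)
        if K.ndim != 2 or K.shape[1] != self.n_train_:
            raise ValueError(
                f"cross kernel must have {self.n_train_} columns, got {K.shape}"
            )
        return self._centerer.transform(K) * self.scale_

    def fit_transform(self, K_train) -> np.ndarray:
        return self.fit(K_train).transform(K_train)


def center_kernel(K_train, K_cross=None) -> np.ndarray:
    """Double-center a kernel; with ``K_cross`` center it w.r.t. training stats.

    For a linear kernel this is algebraically identical to column-centering
    the underlying feature matrix before taking inner products.
    """
    norm = KernelNormalizer(trace_norm=False).fit(K_train)
    if K_cross is None:
        return norm.transform(K_train)
    return norm.transform(K_cross)
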