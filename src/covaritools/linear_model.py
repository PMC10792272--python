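"""Regression primitives used by the reconstruction measures.

Two estimators live here:

:class:`Ridge2FoldCV`
    Ridge regression whose regularizer is chosen by two-fold cross
    validation, accelerated with one thin SVD per fold.  For a half with
    decomposition ``X = U S V^T`` the ridge weights at any ``lam`` are
    ``V diag(s/(s^2+lam)) U^T Y``, so the whole regularizer grid is scored
    by rescaling singular values instead of refitting — the validation
    error for every grid point comes from a single pair of SVDs.

:class:`OrthogonalRegression`
    Orthogonal (Procrustes) regression: the best orthogonal map from one
    centered feature matrix to another.  When the two matrices differ in
    width, the narrower one is padded with zero columns so the map is a
    square orthogonal matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import orthogonal_procrustes, svd

__all__ = [
    "DEFAULT_GRID",
    "Ridge2FoldCV",
    "fit_ridge_2fold",
    "OrthogonalRegression",
    "orthogonal_fit",
]

# 13 geometrically spaced regularizers spanning numerical noise to heavy
# shrinkage; the 2-fold CV picks within this grid by default.
DEFAULT_GRID = np.geomspace(1e-10, 1e2, 13)


def _svd_ridge_weights(X, Y, lam, method="tikhonov"):
    U, s, Vt = svd(X, full_matrices=False)
    if method == "tikhonov":
        d = s / (s**2 + lam)
    elif method == "cutoff":
        d = np.where(s**2 > lam, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    else:
        raise ValueError(f"unknown regularization method {method!r}")
    return Vt.T @ (d[:, None] * (U.T @ Y))


def _two_fold_split(n, seed):
    idx = np.arange(n)
    if seed is not None:
        idx = np.random.default_rng(seed).permutation(n)
    # interleaved split: deterministic and balanced for any n
    return idx[0::2], idx[1::2]


@dataclass
class Ridge2FoldCV:
    """Multi-target ridge with SVD-accelerated two-fold CV over a grid.

    Parameters
    ----------
    grid:
        Candidate regularizers (all > 0).  Ties in validation error break
        toward the smallest value (the least biased model).
    seed:
        ``None`` gives the deterministic even/odd interleaved row split;
        an integer shuffles rows first.
    method:
        ``"tikhonov"`` uses the additive shrinkage ``s/(s^2+lam)``;
        ``"cutoff"`` discards singular values with ``s^2 <= lam`` and
        inverts the rest.
    """

    grid: np.ndarray = None
    seed: int | None = None
    method: str = "tikhonov"
    weights_: np.ndarray = field(default=None, repr=False)
    selected_regularizer_: float = None
    fold_errors_: np.ndarray = field(default=None, repr=False)

    def fit(self, X, Y) -> "Ridge2FoldCV":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = X.shape[0]
        if n < 4:
            raise ValueError("need at least 4 rows for nested 2-fold CV")
        if Y.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        if np.allclose(Y.var(axis=0).sum(), 0):
            raise ValueError("Y has zero variance")
        grid = DEFAULT_GRID if self.grid is None else np.asarray(self.grid, dtype=float)
        if grid.size == 0 or np.any(grid <= 0):
            raise ValueError("grid must be non-empty with positive entries")

        ia, ib = _two_fold_split(n, self.seed)
        errors = np.zeros(grid.size)
        for itr, iva in ((ia, ib), (ib, ia)):
            Xt, Yt, Xv, Yv = X[itr], Y[itr], X[iva], Y[iva]
            U, s, Vt = svd(Xt, full_matrices=False)
            P = Xv @ Vt.T                      # n_val x r
            Q = U.T @ Yt                       # r x q
            denom = np.linalg.norm(Yv) ** 2
            for k, lam in enumerate(grid):
                if self.method == "tikhonov":
                    d = s / (s**2 + lam)
                else:
                    d = np.where(s**2 > lam, 1.0 / np.where(s > 0, s, 1.0), 0.0)
                resid = Yv - P @ (d[:, None] * Q)
                errors[k] += 0.5 * np.linalg.norm(resid) ** 2 / denom
        self.fold_errors_ = errors
        best = int(np.argmin(errors))  # argmin returns the first (smallest lam) tie
        self.selected_regularizer_ = float(grid[best])
        self.grid_ = grid
        self.weights_ = _svd_ridge_weights(X, Y, self.selected_regularizer_, self.method)
        return self

    def predict(self, X) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        return np.asarray(X, dtype=float) @ self.weights_


def fit_ridge_2fold(X, Y, grid=None, seed=None, method="tikhonov") -> Ridge2FoldCV:
    """Functional wrapper: fit and return a :class:`Ridge2FoldCV`."""
    return Ridge2FoldCV(grid=grid, seed=seed, method=method).fit(X, Y)


@dataclass
class OrthogonalRegression:
    """Best orthogonal map between two centered feature matrices.

    Solves ``min_Q ||X Q - Y||_F`` over orthogonal ``Q`` after zero-padding
    the narrower matrix, via ``Q = U V^T`` from the SVD ``X^T Y = U S V^T``.
    Inputs must be column-centered (the orthogonal family contains no
    intercept); a tolerance of 1e-8 on the column means is enforced.
    """

    center_tol: float = 1e-8
    Q_: np.ndarray = field(default=None, repr=False)
    pad_in_: int = 0
    pad_out_: int = 0

    def fit(self, X, Y) -> "OrthogonalRegression":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        for name, M in (("X", X), ("Y", Y)):
            if np.abs(M.mean(axis=0)).max() > self.center_tol:
                raise ValueError(f"matrix {name} is not column-centered")
        width = max(X.shape[1], Y.shape[1])
        self.pad_in_ = width - X.shape[1]
        self.pad_out_ = width - Y.shape[1]
        Xp = np.pad(X, ((0, 0), (0, self.pad_in_)))
        Yp = np.pad(Y, ((0, 0), (0, self.pad_out_)))
        self.Q_, _ = orthogonal_procrustes(Xp, Yp)
        return self

    def predict(self, X) -> np.ndarray:
        if self.Q_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        return np.pad(X, ((0, 0), (0, self.pad_in_))) @ self.Q_


def orthogonal_fit(X, Y) -> OrthogonalRegression:
    """Functional wrapper: fit and return an :class:`OrthogonalRegression`."""
    return OrthogonalRegression().fit(X, Y)
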