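"""Directional convex hull: the lower-bounding surface of a point cloud.

In thermodynamics, the set of phases stable against decomposition is the
lower convex envelope of an (order-parameter, energy) scatter: any point
above the envelope can decompose into a mixture of the envelope points
below it.  This module generalizes that construction to arbitrary numeric
data: pick 1-3 columns of X as the "low-dimensional" coordinates, append
the target y as the vertical axis, take the omnidirectional convex hull
(scipy/Qhull), and keep only the facets whose outward normal points
downward along y.  Those facets form the directional convex hull; their
vertices are the selected samples.

Queries are scored by vertical distance: the hull's target value at the
query's low-dimensional coordinates is interpolated linearly (barycentric
weights on the containing facet) and subtracted from the query's y.  A
zero score means the point lies on the hull; scores are signed so that
out-of-sample points below the hull are detectable.  Queries outside the
hull footprint are flagged with NaN rather than extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "DirectionalConvexHull",
    "fit_dch",
    "dch_score_samples",
    "dch_score_feature_matrix",
]

_NORMAL_TOL = 1e-12
_BARY_TOL = 1e-10


@dataclass
class DirectionalConvexHull:
    """Fitted directional convex hull.

    Attributes
    ----------
    selected_idx_:
        Sorted indices of the samples that are vertices of a downward facet.
    facets_:
        Vertex-index tuples of the downward facets (size d+1 each, where d
        is the number of low-dimensional columns).
    normals_:
        Outward unit normals of those facets in (d+1)-space; their last
        (target-axis) component is negative by construction.
    """

    low_dim_idx: list = field(default_factory=lambda: [0])
    selected_idx_: np.ndarray = None
    facets_: list = None
    normals_: np.ndarray = None
    _points: np.ndarray = field(default=None, repr=False)
    _X_fit: np.ndarray = field(default=None, repr=False)
    _y_fit: np.ndarray = field(default=None, repr=False)

    def fit(self, X, y) -> "DirectionalConvexHull":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        d = len(self.low_dim_idx)
        if not 1 <= d <= 3:
            raise ValueError("the hull supports 1 to 3 low-dimensional columns")
        pts = np.column_stack([X[:, self.low_dim_idx], y])
        if pts.shape[0] < d + 2:
            raise ValueError(f"need at least {d + 2} points for a {d}-D hull")
        try:
            hull = ConvexHull(pts)
        except QhullError as err:
            raise ValueError(
                "convex hull construction failed; the points are degenerate "
                f"(collinear/coplanar): {err}"
            ) from err
        scale = max(np.abs(hull.equations[:, -2]).max(), 1.0)
        down = hull.equations[:, -2] < -_NORMAL_TOL * scale
        facets, normals = [], []
        for simplex, eq in zip(hull.simplices[down], hull.equations[down]):
            facets.append(tuple(int(i) for i in simplex))
            normals.append(eq[:-1])
        if not facets:
            raise ValueError("no downward-facing facets found")
        self.facets_ = facets
        self.normals_ = np.asarray(normals)
        self.selected_idx_ = np.unique(np.concatenate(
            [np.asarray(f) for f in facets]))
        self._points = pts
        self._X_fit = X
        self._y_fit = y
        return self

    def _check_fitted(self):
        if self.selected_idx_ is None:
            raise RuntimeError("hull is not fitted")

    def _locate(self, low):
        """Barycentric weights of each query in its containing facet.

        Returns (facet_index, weights) per query; facet_index -1 flags a
        query outside the hull footprint.
        """
        self._check_fitted()
        low = np.atleast_2d(np.asarray(low, dtype=float))
        d = len(self.low_dim_idx)
        out_f = np.full(low.shape[0], -1, dtype=int)
        out_w = np.zeros((low.shape[0], d + 1))
        for fi, facet in enumerate(self.facets_):
            verts = self._points[list(facet)][:, :d]          # (d+1, d)
            A = np.vstack([verts.T, np.ones(d + 1)])          # (d+1, d+1)
            rhs = np.vstack([low.T, np.ones(low.shape[0])])
            try:
                W = np.linalg.solve(A, rhs).T                 # (nq, d+1)
            except np.linalg.LinAlgError:
                continue
            inside = np.all(W >= -_BARY_TOL, axis=1) & (out_f == -1)
            out_f[inside] = fi
            out_w[inside] = W[inside]
        return out_f, out_w

    def interpolate(self, low):
        """Hull target value at the given low-dimensional coordinates."""
        fidx, W = self._locate(low)
        vals = np.full(fidx.shape[0], np.nan)
        for i, (fi, w) in enumerate(zip(fidx, W)):
            if fi >= 0:
                vals[i] = w @ self._points[list(self.facets_[fi]), -1]
        return vals, fidx

    def score_samples(self, X, y) -> np.ndarray:
        """Signed vertical distance of each sample to the hull surface.

        Zero means on the hull, positive above, negative below.  Samples
        outside the footprint score NaN (a warning is emitted).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        vals, fidx = self.interpolate(X[:, self.low_dim_idx])
        outside = fidx < 0
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} sample(s) outside the hull footprint; "
                "their scores are NaN"
            )
        return y - vals

    def score_feature_matrix(self, X) -> np.ndarray:
        """Residual of the feature columns *not* used to build the hull.

        The unused columns are barycentrically interpolated across the
        containing facet's vertex payload and subtracted from the query's
        values; hull vertices yield zero rows, affine dependencies on the
        hull coordinates are reproduced exactly.
        """
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self._X_fit.shape[1]:
            raise ValueError(
                f"X has {X.shape[1]} columns, hull was fitted with "
                f"{self._X_fit.shape[1]}"
            )
        unused = [j for j in range(X.shape[1]) if j not in self.low_dim_idx]
        fidx, W = self._locate(X[:, self.low_dim_idx])
        if (fidx < 0).any():
            warnings.warn(
                f"{int((fidx < 0).sum())} sample(s) outside the hull "
                "footprint; their residual rows are NaN"
            )
        out = np.full((X.shape[0], len(unused)), np.nan)
        payload = self._X_fit[:, unused]
        for i, (fi, w) in enumerate(zip(fidx, W)):
            if fi >= 0:
                out[i] = X[i, unused] - w @ payload[list(self.facets_[fi])]
        return out


def fit_dch(X, y, low_dim_idx=(0,)) -> DirectionalConvexHull:
    """Fit a :class:`DirectionalConvexHull` on the chosen columns of X."""
    return DirectionalConvexHull(low_dim_idx=list(low_dim_idx)).fit(X, y)


def dch_score_samples(hull: DirectionalConvexHull, X, y) -> np.ndarray:
    return hull.score_samples(X, y)


def dch_score_feature_matrix(hull: DirectionalConvexHull, X) -> np.ndarray:
    return hull.score_feature_matrix(X)
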