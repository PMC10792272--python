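"""Greedy feature and sample selection: FPS, Voronoi-FPS and CUR.

Farthest point sampling (FPS) grows a subset by repeatedly adding the
candidate farthest from the already-selected set; the per-candidate score is
the min-distance-to-selected (the Hausdorff score).  CUR ranks candidates by
the leverage score pi — the squared projection onto the top-k singular
vectors of the current matrix — and orthogonalizes the remainder after each
pick so later picks carry new information.

Both have supervised hybrids controlled by a mixing parameter ``alpha``:
distances (FPS) or eigenvectors (CUR) are taken from the PCov-modified Gram
matrix ``alpha X X^T + (1-alpha) Yhat Yhat^T`` for sample selection, or the
analogously modified covariance for feature selection.  ``alpha = 1``
reduces exactly to the unsupervised algorithms.

Voronoi-FPS returns results identical to plain FPS but skips distance
computations using the implicit Voronoi tessellation of the selected
centers: after adding a center ``c*``, candidates owned by center ``c`` can
only change owner when ``d(c, c*) < 2 * radius(c)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, svd
from scipy.spatial.distance import cdist
from sklearn.linear_model import Ridge

__all__ = [
    "SelectionResult",
    "fps_select",
    "voronoi_fps_select",
    "cur_select",
    "selector_score",
]

_DEGENERATE_TOL = 1e-12


def _progress_bar(progress, total, done):
    if not progress:
        return None
    from tqdm import tqdm

    return tqdm(total=total, initial=done, desc="selecting")


@dataclass
class SelectionResult:
    """Outcome of a greedy selection run.

    ``selection_scores`` aligns with ``selected_idx_``; entries supplied via
    ``initialize`` carry ``inf`` (they were not chosen by score).
    ``final_scores`` is the score of every candidate after the last pick
    (FPS: Hausdorff distance, 0 for selected; CUR: leverage, selected
    masked to 0).
    """

    axis: str
    selected_idx_: np.ndarray
    selection_scores: np.ndarray
    final_scores: np.ndarray
    terminated_by: str
    method: str = "fps"
    n_distance_evaluations: int = 0
    skipped_degenerate: list = field(default_factory=list)


def selector_score(result: SelectionResult, X=None) -> np.ndarray:
    """Scores of all candidates in the context of the finished selection."""
    if result.final_scores is None:
        raise RuntimeError("selection result carries no scores")
    return result.final_scores


def _candidate_matrix(X, axis):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if axis == "samples":
        return X
    if axis == "features":
        return X.T
    raise ValueError(f"axis must be 'samples' or 'features', got {axis!r}")


def _resolve_yhat(X, Y, Yhat):
    if Yhat is not None:
        Yhat = np.asarray(Yhat, dtype=float)
        return Yhat[:, None] if Yhat.ndim == 1 else Yhat
    if Y is None:
        raise ValueError("mixing < 1 requires targets (Y or Yhat)")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    reg = Ridge(alpha=1e-8, fit_intercept=False).fit(X, Y)
    return X @ np.atleast_2d(reg.coef_).T if reg.coef_.ndim == 1 else reg.predict(X)


def _pinv_sqrt(C):
    w, V = eigh((C + C.T) / 2)
    cutoff = 1e-12 * max(w[-1], 0.0)
    d = np.where(w > cutoff, 1.0 / np.sqrt(np.where(w > cutoff, w, 1.0)), 0.0)
    return (V * d) @ V.T


def _pcov_metric_matrix(X, axis, mixing, Y, Yhat):
    """Modified Gram (samples) or covariance (features) inducing the metric."""
    X = np.asarray(X, dtype=float)
    Yhat = _resolve_yhat(X, Y, Yhat)
    a = mixing
    if axis == "samples":
        return a * (X @ X.T) + (1 - a) * (Yhat @ Yhat.T)
    C = X.T @ X
    B = _pinv_sqrt(C) @ (X.T @ Yhat)
    return a * C + (1 - a) * (B @ B.T)


def _init_indices(initialize, n, seed):
    if initialize is None:
        if seed is None:
            raise ValueError(
                "provide an explicit `initialize` index list or a `seed` for "
                "a random starting point"
            )
        return [int(np.random.default_rng(seed).integers(n))]
    init = [int(i) for i in np.atleast_1d(initialize)]
    if not init:
        raise ValueError("initialize must be non-empty")
    for i in init:
        if not 0 <= i < n:
            raise IndexError(f"initialize index {i} out of bounds for size {n}")
    return init


class _EuclideanDistance:
    """Distances between candidate rows; counts scalar distance evaluations."""

    def __init__(self, V):
        self.V = V
        self.count = 0

    def to_center(self, center, subset=None):
        rows = self.V if subset is None else self.V[subset]
        d = cdist(rows, self.V[center][None, :]).ravel()
        self.count += d.size
        return d


class _PCovDistance:
    """Distances induced by a PCov-modified Gram/covariance matrix M:
    d^2(i, j) = M_ii + M_jj - 2 M_ij."""

    def __init__(self, M):
        self.M = M
        self.diag = np.diag(M).copy()
        self.count = 0

    def to_center(self, center, subset=None):
        idx = slice(None) if subset is None else subset
        d2 = self.diag[idx] + self.diag[center] - 2 * self.M[idx, center]
        d = np.sqrt(np.maximum(d2, 0.0))
        self.count += d.size
        return d


def _fps_core(dist, n, n_to_select, init, score_threshold, axis, method,
              progress=False):
    hausdorff = np.full(n, np.inf)
    in_set = np.zeros(n, dtype=bool)
    selected, scores = [], []
    for i in init:
        if len(selected) >= n_to_select or in_set[i]:
            continue
        selected.append(i)
        scores.append(np.inf)
        in_set[i] = True
        hausdorff = np.minimum(hausdorff, dist.to_center(i))
    terminated = "n_to_select"
    pbar = _progress_bar(progress, n_to_select, len(selected))
    while len(selected) < n_to_select:
        best = int(np.argmax(np.where(in_set, -np.inf, hausdorff)))
        best_score = float(hausdorff[best])
        if score_threshold is not None and best_score < score_threshold:
            terminated = "score_threshold"
            break
        selected.append(best)
        scores.append(best_score)
        in_set[best] = True
        hausdorff = np.minimum(hausdorff, dist.to_center(best))
        if pbar:
            pbar.update(1)
    if pbar:
        pbar.close()
    if len(selected) == n:
        terminated = "exhausted"
    return SelectionResult(
        axis=axis,
        selected_idx_=np.asarray(selected, dtype=int),
        selection_scores=np.asarray(scores, dtype=float),
        final_scores=hausdorff,
        terminated_by=terminated,
        method=method,
        n_distance_evaluations=dist.count,
    )


def fps_select(X, axis="samples", n_to_select=None, initialize=None,
               score_threshold=None, mixing=1.0, Y=None, Yhat=None,
               seed=None, progress=False) -> SelectionResult:
    """Farthest point sampling over rows (samples) or columns (features).

    With ``mixing < 1`` (PCov-FPS) the distance is induced by the modified
    Gram/covariance matrix; the predicted targets are computed once up
    front (pass ``Yhat`` to supply them directly).  Ties break toward the
    smallest index.
    """
    V = _candidate_matrix(X, axis)
    n = V.shape[0]
    if n == 0:
        raise ValueError("empty candidate set")
    n_to_select = n if n_to_select is None else int(n_to_select)
    if not 1 <= n_to_select <= n:
        raise ValueError(f"n_to_select must be in [1, {n}]")
    init = _init_indices(initialize, n, seed)
    if mixing == 1.0:
        dist = _EuclideanDistance(V)
    else:
        if not 0.0 <= mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")
        M = _pcov_metric_matrix(X, axis, mixing, Y, Yhat)
        dist = _PCovDistance(M)
    method = "fps" if mixing == 1.0 else "pcov-fps"
    return _fps_core(dist, n, n_to_select, init, score_threshold, axis, method,
                     progress=progress)


def voronoi_fps_select(X, n_to_select=None, initialize=None,
                       score_threshold=None, seed=None) -> SelectionResult:
    """FPS over samples with Voronoi short-circuiting.

    Produces the same indices and scores as :func:`fps_select` (samples
    axis, ``mixing=1``) while evaluating strictly fewer distances on
    clustered data; ``n_distance_evaluations`` records the count.
    """
    V = _candidate_matrix(X, "samples")
    n = V.shape[0]
    if n == 0:
        raise ValueError("empty candidate set")
    n_to_select = n if n_to_select is None else int(n_to_select)
    if not 1 <= n_to_select <= n:
        raise ValueError(f"n_to_select must be in [1, {n}]")
    init = _init_indices(initialize, n, seed)
    dist = _EuclideanDistance(V)

    hausdorff = np.full(n, np.inf)
    owner = np.full(n, -1)
    in_set = np.zeros(n, dtype=bool)
    selected, scores = [], []
    for i in init:
        if len(selected) >= n_to_select or in_set[i]:
            continue
        selected.append(i)
        scores.append(np.inf)
        in_set[i] = True
        d = dist.to_center(i)
        closer = d < hausdorff
        hausdorff[closer] = d[closer]
        owner[closer] = i

    terminated = "n_to_select"
    while len(selected) < n_to_select:
        best = int(np.argmax(np.where(in_set, -np.inf, hausdorff)))
        best_score = float(hausdorff[best])
        if score_threshold is not None and best_score < score_threshold:
            terminated = "score_threshold"
            break
        centers = np.asarray(selected)
        # a cell can lose members only if its center is close enough to the
        # new center: d(c, c*) < 2 * radius(c)
        d_centers = dist.to_center(best, subset=centers)
        radius = np.zeros(len(centers))
        for k, c in enumerate(centers):
            members = owner == c
            if members.any():
                radius[k] = hausdorff[members].max()
        active = centers[d_centers < 2 * radius]
        if active.size:
            cand = np.flatnonzero(np.isin(owner, active))
            d = dist.to_center(best, subset=cand)
            closer = d < hausdorff[cand]
            upd = cand[closer]
            hausdorff[upd] = d[closer]
            owner[upd] = best
        selected.append(best)
        scores.append(best_score)
        in_set[best] = True
        hausdorff[best] = 0.0
        owner[best] = best
    if len(selected) == n:
        terminated = "exhausted"
    return SelectionResult(
        axis="samples",
        selected_idx_=np.asarray(selected, dtype=int),
        selection_scores=np.asarray(scores, dtype=float),
        final_scores=hausdorff,
        terminated_by=terminated,
        method="voronoi-fps",
        n_distance_evaluations=dist.count,
    )


def _leverage_scores(A, k, mixing, Y, axis):
    """Leverage pi of each candidate row of A along the top-k directions."""
    if mixing == 1.0:
        U, s, Vt = svd(A, full_matrices=False)
        rank = int(np.sum(s > _DEGENERATE_TOL * max(s[0], 1.0)))
        if k > rank:
            raise ValueError(f"k={k} exceeds the current rank {rank}")
        return np.sum(U[:, :k] ** 2, axis=1)
    if axis == "features":
        # A rows are features: X = A.T
        M = _pcov_metric_matrix(A.T, "features", mixing, Y, None)
    else:
        M = _pcov_metric_matrix(A, "samples", mixing, Y, None)
    w, V = eigh((M + M.T) / 2)
    order = np.argsort(w, kind="stable")[::-1]
    w, V = w[order], V[:, order]
    rank = int(np.sum(w > _DEGENERATE_TOL * max(w[0], 1.0)))
    if k > rank:
        raise ValueError(f"k={k} exceeds the current rank {rank}")
    return np.sum(V[:, :k] ** 2, axis=1)


def cur_select(X, axis="features", n_to_select=None, k=1, recompute_every=1,
               score_threshold=None, mixing=1.0, Y=None) -> SelectionResult:
    """Greedy CUR selection by leverage score with iterative orthogonalization.

    After each pick the remaining candidates are orthogonalized to the
    selected one; for PCov-CUR on the feature axis the targets are deflated
    by the variance the selected column explains.  ``pi`` is recomputed
    every ``recompute_every`` picks; in between the stale scores are reused
    with selected entries masked.
    """
    A = _candidate_matrix(X, axis).copy()
    n = A.shape[0]
    if n == 0:
        raise ValueError("empty candidate set")
    n_to_select = n if n_to_select is None else int(n_to_select)
    if not 1 <= n_to_select <= n:
        raise ValueError(f"n_to_select must be in [1, {n}]")
    if recompute_every < 1:
        raise ValueError("recompute_every must be >= 1")
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing must lie in [0, 1]")
    if mixing < 1.0 and Y is None:
        raise ValueError("mixing < 1 requires targets Y")
    Ycur = None
    if Y is not None:
        Ycur = np.asarray(Y, dtype=float).copy()
        if Ycur.ndim == 1:
            Ycur = Ycur[:, None]

    selected, scores, skipped = [], [], []
    mask = np.zeros(n, dtype=bool)
    pi = None
    since_recompute = 0
    terminated = "n_to_select"
    while len(selected) < n_to_select:
        if pi is None or since_recompute >= recompute_every:
            pi = _leverage_scores(A, k, mixing, Ycur, axis)
            since_recompute = 0
        live = np.where(mask, -np.inf, pi)
        norms = np.linalg.norm(A, axis=1)
        live[norms <= _DEGENERATE_TOL] = -np.inf
        degenerate = (~mask) & (norms <= _DEGENERATE_TOL)
        if degenerate.any():
            skipped.extend(np.flatnonzero(degenerate).tolist())
            mask |= degenerate
        if not np.isfinite(live).any():
            terminated = "exhausted"
            break
        best = int(np.argmax(live))
        best_score = float(pi[best])
        if score_threshold is not None and best_score < score_threshold:
            terminated = "score_threshold"
            break
        selected.append(best)
        scores.append(best_score)
        mask[best] = True
        a = A[best].copy()
        na2 = a @ a
        if na2 > 0:
            A -= np.outer(A @ a, a) / na2
            if axis == "features" and Ycur is not None:
                # column x_j of X is the selected feature's sample vector = a
                Ycur -= np.outer(a, a @ Ycur) / na2
        A[best] = 0.0
        since_recompute += 1
    if mask.all() and terminated == "n_to_select" and len(selected) < n:
        terminated = "exhausted"
    if len(selected) == n:
        terminated = "exhausted"
    final = np.where(mask, 0.0, pi if pi is not None else 0.0)
    return SelectionResult(
        axis=axis,
        selected_idx_=np.asarray(selected, dtype=int),
        selection_scores=np.asarray(scores, dtype=float),
        final_scores=np.asarray(final, dtype=float),
        terminated_by=terminated,
        method="cur" if mixing == 1.0 else "pcov-cur",
        skipped_degenerate=skipped,
    )
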