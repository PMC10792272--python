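"""Feature reconstruction measures.

Given two featurizations F and G of the same samples, these measures ask how
much of G is recoverable from F under a constrained family of maps:

- GFRE (global feature reconstruction error): ridge regression F -> G.
  Measures linearly decodable information.
- GFRD (global feature reconstruction distortion): the map is restricted to
  be orthogonal (after zero-padding to equal width), so any residual error
  reflects the geometric deformation needed to align the two spaces.
- LFRE (local feature reconstruction error): an independent ridge fit on the
  k nearest training neighbours of each test point, capturing information
  that is only locally (nonlinearly) decodable.

All three share one protocol.  Rows are split into two folds; within a fold
the features of F and G are standardised with statistics of the training
rows only, the constrained map is fitted on the training rows, and the
normalized test error

    fold value = sqrt( sum_test ||g_i - ghat_i||^2 / sum_test ||g_i||^2 )

is computed.  The reported value is the root mean square of the two fold
values.  Because G is centered and globally scaled on the training rows,
the trivial zero predictor scores exactly 1: values near 0 mean perfect
reconstruction, values near 1 mean no linearly (or locally) usable signal.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .linear_model import Ridge2FoldCV, orthogonal_fit
from .preprocessing import FeatureScaler

__all__ = ["ReconstructionReport", "gfre", "gfrd", "lfre", "noise_floor"]


@dataclass
class ReconstructionReport:
    """Result of a feature reconstruction measure.

    ``pointwise`` (when requested) holds one non-negative contribution per
    test sample, normalized so that ``value == sqrt(pointwise.sum())``:
    sample i in fold f contributes ``||g_i - ghat_i||^2 / (2 * D_f)`` where
    ``D_f`` is the fold's total test norm ``sum ||g||^2``.
    """

    value: float
    per_fold: np.ndarray
    direction: tuple
    n_local_points: int | None = None
    pointwise: np.ndarray = field(default=None, repr=False)
    pointwise_index: np.ndarray = field(default=None, repr=False)
    warnings_: list = field(default_factory=list, repr=False)


def _check_pair(F, G, n_min):
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    if G.ndim == 1:
        G = G[:, None]
    if F.shape[0] != G.shape[0]:
        raise ValueError("F and G must have the same number of rows")
    if F.shape[0] < n_min:
        raise ValueError(f"need at least {n_min} rows, got {F.shape[0]}")
    return F, G


def _outer_folds(n, seed):
    idx = np.arange(n)
    if seed is not None:
        idx = np.random.default_rng(seed).permutation(n)
    a, b = idx[0::2], idx[1::2]
    return [(a, b), (b, a)]


def _make_scaler(scaler):
    if scaler is None:
        return FeatureScaler(mode="global")
    return copy.deepcopy(scaler)


def _aggregate(fold_values, fold_nums, fold_dens, fold_test_idx, want_pointwise,
               direction, n_local_points=None, warn=()):
    per_fold = np.asarray(fold_values)
    value = float(np.sqrt(np.mean(per_fold**2)))
    pointwise = index = None
    if want_pointwise:
        parts, idxs = [], []
        for nums, den, tix in zip(fold_nums, fold_dens, fold_test_idx):
            parts.append(np.asarray(nums) / (len(fold_values) * den))
            idxs.append(tix)
        pointwise = np.concatenate(parts)
        index = np.concatenate(idxs)
    return ReconstructionReport(
        value=value, per_fold=per_fold, direction=direction,
        n_local_points=n_local_points, pointwise=pointwise,
        pointwise_index=index, warnings_=list(warn),
    )


def _fold_scaled(F, G, train, scaler):
    sf = _make_scaler(scaler).fit(F[train])
    sg = _make_scaler(scaler).fit(G[train])
    return sf.transform(F), sg.transform(G)


def gfre(F, G, grid=None, seed=None, pointwise=False, scaler=None,
         estimator=None) -> ReconstructionReport:
    """Global feature reconstruction error of G from F (ridge map)."""
    F, G = _check_pair(F, G, n_min=8)
    fold_values, nums_all, dens_all, test_all = [], [], [], []
    for train, test in _outer_folds(F.shape[0], seed):
        Fs, Gs = _fold_scaled(F, G, train, scaler)
        if estimator is None:
            est = Ridge2FoldCV(grid=grid, seed=seed)
        else:
            est = copy.deepcopy(estimator)
        est.fit(Fs[train], Gs[train])
        resid = Gs[test] - est.predict(Fs[test])
        nums = np.sum(resid**2, axis=1)
        den = np.sum(Gs[test] ** 2)
        fold_values.append(np.sqrt(nums.sum() / den))
        nums_all.append(nums)
        dens_all.append(den)
        test_all.append(test)
    return _aggregate(fold_values, nums_all, dens_all, test_all, pointwise,
                      ("F", "G"))


def gfrd(F, G, seed=None, pointwise=False, scaler=None) -> ReconstructionReport:
    """Global feature reconstruction distortion (orthogonal map).

    The train rows are exactly centered by the fold scaler, so the
    orthogonal fit's centering precondition holds by construction.  Width
    mismatches are handled by zero-padding; the error is measured in the
    padded space (the denominator is unchanged by zero columns).
    """
    F, G = _check_pair(F, G, n_min=8)
    fold_values, nums_all, dens_all, test_all = [], [], [], []
    for train, test in _outer_folds(F.shape[0], seed):
        Fs, Gs = _fold_scaled(F, G, train, scaler)
        model = orthogonal_fit(Fs[train], Gs[train])
        pred = model.predict(Fs[test])
        target = np.pad(Gs[test], ((0, 0), (0, model.pad_out_)))
        resid = target - pred
        nums = np.sum(resid**2, axis=1)
        den = np.sum(Gs[test] ** 2)
        fold_values.append(np.sqrt(nums.sum() / den))
        nums_all.append(nums)
        dens_all.append(den)
        test_all.append(test)
    return _aggregate(fold_values, nums_all, dens_all, test_all, pointwise,
                      ("F", "G"))


def lfre(F, G, n_local_points, grid=None, seed=None, pointwise=False,
         scaler=None) -> ReconstructionReport:
    """Local feature reconstruction error with k-nearest-neighbour ridge fits.

    For every test point the ``n_local_points`` nearest training rows (in
    the scaled F space) form a neighbourhood; both F and G are centered on
    the neighbourhood means, a ridge map is fitted there, and the test
    prediction adds the neighbourhood mean back — an affine local map.
    """
    F, G = _check_pair(F, G, n_min=8)
    k = int(n_local_points)
    if k < 4:
        raise ValueError("n_local_points must be at least 4 for the nested CV")
    warn = []
    if k < F.shape[1] + 1:
        msg = (f"n_local_points={k} < p_F+1={F.shape[1] + 1}: "
               "local fits are underdetermined")
        warn.append(msg)
        warnings.warn(msg)
    fold_values, nums_all, dens_all, test_all = [], [], [], []
    for train, test in _outer_folds(F.shape[0], seed):
        if k > train.size:
            raise ValueError(
                f"n_local_points={k} exceeds the training split size {train.size}"
            )
        Fs, Gs = _fold_scaled(F, G, train, scaler)
        Ftr, Gtr = Fs[train], Gs[train]
        D = cdist(Fs[test], Ftr)
        nums = np.empty(test.size)
        for j in range(test.size):
            nbh = np.argsort(D[j], kind="stable")[:k]
            Fn, Gn = Ftr[nbh], Gtr[nbh]
            fmean, gmean = Fn.mean(axis=0), Gn.mean(axis=0)
            est = Ridge2FoldCV(grid=grid, seed=seed)
            est.fit(Fn - fmean, Gn - gmean)
            ghat = gmean + est.predict(Fs[test[j]][None, :] - fmean)[0]
            nums[j] = np.sum((Gs[test[j]] - ghat) ** 2)
        den = np.sum(Gs[test] ** 2)
        fold_values.append(np.sqrt(nums.sum() / den))
        nums_all.append(nums)
        dens_all.append(den)
        test_all.append(test)
    return _aggregate(fold_values, nums_all, dens_all, test_all, pointwise,
                      ("F", "G"), n_local_points=k, warn=warn)


def noise_floor(F, grid=None, seed=None) -> float:
    """Numerical noise floor of the reconstruction protocol.

    The GFRE of the identity relation (F reconstructed from F itself) is
    nonzero only through solver round-off and CV shrinkage; its value is
    the resolution below which two measured reconstruction errors cannot
    be meaningfully distinguished.
    """
    return gfre(F, F, grid=grid, seed=seed).value
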