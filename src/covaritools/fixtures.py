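"""Deterministic synthetic data generators with planted ground truth.

Each generator emulates one structural assumption the estimators in this
package rely on — a planted low-rank linear model, feature pairs with a
known mutual relationship, separable class blobs, concentric rings, and
point clouds with a known lower convex envelope — so that every algorithm
can be exercised and validated without external datasets.  Generators are
pure functions of their arguments: the random stream is derived from
``(seed, generator-name)``, so the same call always returns bit-identical
data and adding a new generator never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixtureBundle",
    "make_lowrank_regression",
    "make_feature_pair",
    "make_labeled_blobs",
    "make_rings",
    "make_hull_cloud",
]

FEATURE_PAIR_RELATIONS = ("rotation", "shear", "nested", "nonlinear")


@dataclass
class FixtureBundle:
    """A generated dataset plus its planted ground truth."""

    matrices: dict
    ground_truth: dict = field(default_factory=dict)
    seed: int = 0
    descriptor: str = ""

    def __getitem__(self, key):
        return self.matrices[key]


def _rng(seed, name):
    # independent stream per (seed, generator-name)
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


def _random_orthogonal(rng, p):
    Q, R = np.linalg.qr(rng.standard_normal((p, p)))
    return Q * np.sign(np.diag(R))


def make_lowrank_regression(n=200, p=8, r=4, q=1, noise_sd=0.0,
                            seed=0) -> FixtureBundle:
    """Rank-r features X = A @ B with a planted linear target Y = X w + eps."""
    if r > min(n, p):
        raise ValueError(f"rank r={r} exceeds min(n, p)={min(n, p)}")
    rng = _rng(seed, "lowrank_regression")
    A = rng.standard_normal((n, r))
    B = rng.standard_normal((r, p))
    X = A @ B
    w = rng.standard_normal((p, q))
    Y = X @ w + noise_sd * rng.standard_normal((n, q))
    return FixtureBundle(
        matrices={"X": X, "Y": Y},
        ground_truth={"weights": w, "rank": r, "noise_sd": noise_sd},
        seed=seed,
        descriptor=f"planted low-rank regression n={n} p={p} r={r} q={q}",
    )


def make_feature_pair(n=500, p_shared=3, p_extra=3, relation="rotation",
                      seed=0) -> FixtureBundle:
    """Two featurizations (F, G) of one dataset with a declared relationship.

    rotation:  G = F @ R with R orthogonal (losslessly, rigidly related)
    shear:     G = F @ A with A a unit upper-triangular shear
    nested:    G = [F @ R | H] with H independent Gaussian columns
    nonlinear: F = t (a 1-D parameter), G = [t, 0.3 t^2] (curved manifold)
    """
    if relation not in FEATURE_PAIR_RELATIONS:
        raise ValueError(
            f"unknown relation {relation!r}; choose from {FEATURE_PAIR_RELATIONS}"
        )
    if n <= 8 * (p_shared + p_extra):
        raise ValueError("n must exceed 8 * (p_shared + p_extra)")
    rng = _rng(seed, f"feature_pair_{relation}")
    if relation == "nonlinear":
        t = rng.uniform(-3.0, 3.0, size=(n, 1))
        F = t
        G = np.column_stack([t.ravel(), 0.3 * t.ravel() ** 2])
        return FixtureBundle(
            matrices={"F": F, "G": G},
            ground_truth={"t": t.ravel(), "curvature": 0.3},
            seed=seed,
            descriptor=f"1-D manifold embedded in 2-D, n={n}",
        )
    F = rng.standard_normal((n, p_shared))
    if relation == "rotation":
        R = _random_orthogonal(rng, p_shared)
        G = F @ R
        gt = {"R": R}
    elif relation == "shear":
        A = np.triu(np.ones((p_shared, p_shared)))
        G = F @ A
        gt = {"A": A}
    else:  # nested
        R = _random_orthogonal(rng, p_shared)
        H = rng.standard_normal((n, p_extra))
        G = np.column_stack([F @ R, H])
        gt = {"R": R, "p_extra": p_extra}
    return FixtureBundle(
        matrices={"F": F, "G": G},
        ground_truth=gt,
        seed=seed,
        descriptor=f"feature pair relation={relation} n={n} p={p_shared}",
    )


def make_labeled_blobs(n=400, n_classes=2, separation=6.0, p=2, seed=0,
                       nuisance_scale=1.0) -> FixtureBundle:
    """Unit-variance Gaussian blobs with class means on a scaled simplex.

    ``separation`` is the distance between class means in units of the
    within-class standard deviation; 6 makes classes linearly separable in
    practice.  Labels are balanced to within one count.

    The class means span only the first ``n_classes - 1`` coordinates; the
    remaining coordinates carry no class information and their standard
    deviation is ``nuisance_scale``.  Values above 1 emulate datasets whose
    dominant variance directions are unrelated to the labels — the regime
    where purely unsupervised dimensionality reduction discards the class
    structure.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if n < n_classes:
        raise ValueError("need at least one sample per class")
    if p < n_classes - 1:
        raise ValueError("p must be at least n_classes - 1 to place the simplex")
    rng = _rng(seed, "labeled_blobs")
    # regular simplex directions with pairwise distance `separation`
    corners = np.zeros((n_classes, p))
    corners[:, : max(n_classes - 1, 1)] = _simplex_vertices(n_classes)[:, : p]
    means = corners * separation
    labels = np.arange(n) % n_classes
    scales = np.ones(p)
    scales[max(n_classes - 1, 1):] = nuisance_scale
    X = means[labels] + rng.standard_normal((n, p)) * scales
    order = rng.permutation(n)
    return FixtureBundle(
        matrices={"X": X[order], "labels": labels[order]},
        ground_truth={"means": means, "separation": separation},
        seed=seed,
        descriptor=f"{n_classes} Gaussian blobs, separation={separation} sigma",
    )


def _simplex_vertices(k):
    """k vertices of a regular simplex with unit pairwise distance."""
    V = np.eye(k) / np.sqrt(2)
    V -= V.mean(axis=0)
    # rotate into k-1 dimensions
    U, s, _ = np.linalg.svd(V, full_matrices=False)
    return U[:, : k - 1] * s[: k - 1]


def make_rings(n=400, radii=(1.0, 3.0), noise_sd=0.1, seed=0) -> FixtureBundle:
    """Concentric 2-D annuli, one class per radius (not linearly separable)."""
    radii = tuple(float(r) for r in radii)
    if n < len(radii):
        raise ValueError("need at least one sample per ring")
    rng = _rng(seed, "rings")
    labels = np.arange(n) % len(radii)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    r = np.asarray(radii)[labels] + noise_sd * rng.standard_normal(n)
    X = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    order = rng.permutation(n)
    return FixtureBundle(
        matrices={"X": X[order], "labels": labels[order]},
        ground_truth={"radii": radii, "noise_sd": noise_sd},
        seed=seed,
        descriptor=f"concentric rings radii={radii} n={n}",
    )


def make_hull_cloud(n=100, n_vertices=5, seed=0) -> FixtureBundle:
    """A 2-D cloud with a known lower convex envelope.

    ``n_vertices`` points sit exactly on a strictly convex parabola (so all
    of them are envelope vertices, including both x-extremes); the other
    points lie strictly above it.  The true vertex index set is stored in
    the ground truth.
    """
    if n_vertices < 3:
        raise ValueError("need at least 3 hull vertices")
    if n < n_vertices:
        raise ValueError("n must be at least n_vertices")
    rng = _rng(seed, "hull_cloud")
    xv = np.linspace(-2.0, 2.0, n_vertices)
    yv = 0.5 * xv**2
    n_above = n - n_vertices
    xa = rng.uniform(-2.0, 2.0, size=n_above)
    ya = 0.5 * xa**2 + rng.uniform(0.1, 2.0, size=n_above)
    x = np.concatenate([xv, xa])
    y = np.concatenate([yv, ya])
    order = rng.permutation(n)
    x, y = x[order], y[order]
    vertex_idx = np.flatnonzero(np.isin(order, np.arange(n_vertices)))
    return FixtureBundle(
        matrices={"X": x[:, None], "y": y},
        ground_truth={"vertex_idx": np.sort(vertex_idx)},
        seed=seed,
        descriptor=f"parabolic lower-hull cloud n={n} vertices={n_vertices}",
    )
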