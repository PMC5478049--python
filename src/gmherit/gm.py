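"""Generalized Procrustes analysis, tangent-space PCA and static allometry.

Shapes are 2-D landmark configurations. GPA removes location, scale and
rotation; what remains lives (to first order) in the tangent space to shape
space at the consensus, where ordinary PCA and linear regression on centroid
size are valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import warnings

import numpy as np

from .io import LandmarkConfiguration

__all__ = [
    "AlignedShapeSet",
    "ShapePCA",
    "AllometryModel",
    "centroid_size",
    "gpa_align",
    "tangent_pca",
    "fit_allometry",
]


def centroid_size(config: "LandmarkConfiguration | np.ndarray") -> float:
    """Centroid size: square root of the summed squared distances of the
    landmarks to their centroid.

    Translation- and rotation-invariant; scales linearly under uniform
    scaling.  Raises ``ValueError`` for a degenerate (all-coincident)
    configuration, whose size would be zero.
    """
    xy = np.asarray(getattr(config, "landmarks", config), dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ValueError("need a (k, 2) array with k >= 2 landmarks")
    centered = xy - xy.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size <= 0.0 or not np.isfinite(size):
        raise ValueError("all landmarks coincide: centroid size is zero")
    return size


@dataclass
class AlignedShapeSet:
    """Procrustes-aligned configurations.

    ``aligned`` holds n configurations of (k, 2) Procrustes coordinates, each
    centered at the origin with unit centroid size. ``centroid_sizes`` are
    the sizes of the raw configurations before scaling. ``consensus`` is the
    coordinate-wise mean of the aligned configurations.
    """

    consensus: np.ndarray
    aligned: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    converged: bool
    iterations: int
    specimen_ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened to (n, 2k), x1,y1,...,xk,yk order."""
        return self.aligned.reshape(self.n, -1)


def _optimal_rotations(configs: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Closed-form 2-D rotations aligning each config to ``target``.

    For centered X (config) and Y (target) the rotation maximizing
    tr(R X^T Y) is R = [[c, -s], [s, c]] with (c, s) proportional to
    (sum x.y, sum x cross y) — the 2-D special case of the SVD solution,
    determinant forced +1 (no reflection: landmarks have fixed chirality).
    Returns rotated copies of ``configs``.
    """
    # a = <X, Y>, b = sum of 2-D cross products x_i × y_i
    a = np.einsum("nki,ki->n", configs, target)
    b = (configs[:, :, 0] * target[None, :, 1]
         - configs[:, :, 1] * target[None, :, 0]).sum(axis=1)
    norm = np.hypot(a, b)
    # a = b = 0 only if a config is orthogonal to the target in both senses;
    # leave such a config unrotated.
    safe = norm > 0
    c = np.where(safe, a / np.where(safe, norm, 1.0), 1.0)
    s = np.where(safe, b / np.where(safe, norm, 1.0), 0.0)
    x, y = configs[:, :, 0], configs[:, :, 1]
    out = np.empty_like(configs)
    out[:, :, 0] = c[:, None] * x - s[:, None] * y
    out[:, :, 1] = s[:, None] * x + c[:, None] * y
    return out


def _canonical_orientation(shapes: np.ndarray) -> np.ndarray:
    """Rotate the whole aligned set to a deterministic orientation.

    The consensus is put on its principal axes (major axis along x, det +1)
    and the residual 180-degree ambiguity is fixed by making the consensus
    element of largest magnitude positive.  This makes GPA output independent
    of specimen order (the iteration starts from the first specimen).
    """
    consensus = shapes.mean(axis=0)
    m = consensus.T @ consensus
    _, vecs = np.linalg.eigh(m)  # ascending: minor axis first
    q = vecs[:, ::-1]
    if np.linalg.det(q) < 0:
        q[:, 1] = -q[:, 1]
    rotated = shapes @ q
    cons = consensus @ q
    flat = cons.reshape(-1)
    if flat[np.argmax(np.abs(flat))] < 0:
        rotated = -rotated
    return rotated


def gpa_align(
    configs: Sequence[LandmarkConfiguration] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapeSet:
    """Generalized Procrustes alignment of 2-D landmark configurations.

    Each configuration is centered, scaled to unit centroid size and
    iteratively rotated to the current consensus (the renormalized mean
    shape) until the consensus changes by less than ``tol`` in Frobenius
    norm, or ``max_iter`` is reached (then ``converged`` is False and a
    warning is emitted).
    """
    ids: list = []
    if isinstance(configs, np.ndarray):
        arr = np.asarray(configs, dtype=float)
    else:
        configs = list(configs)
        if len(configs) and hasattr(configs[0], "landmarks"):
            ids = [c.specimen_id for c in configs]
            arr = np.stack([np.asarray(c.landmarks, float) for c in configs])
        else:
            arr = np.stack([np.asarray(c, float) for c in configs])
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError("expected an (n, k, 2) landmark array")
    n, k = arr.shape[0], arr.shape[1]
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")

    centered = arr - arr.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.einsum("nki->n", centered**2))
    if np.any(sizes <= 0):
        bad = int(np.argmin(sizes))
        raise ValueError(f"configuration {bad} is degenerate (zero centroid size)")
    shapes = centered / sizes[:, None, None]

    consensus = shapes[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        shapes = _optimal_rotations(shapes, consensus)
        new_consensus = shapes.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        delta = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", RuntimeWarning
        )
    shapes = _canonical_orientation(shapes)
    return AlignedShapeSet(
        consensus=shapes.mean(axis=0),
        aligned=shapes,
        centroid_sizes=sizes,
        converged=converged,
        iterations=it,
        specimen_ids=ids,
    )


@dataclass
class ShapePCA:
    """Tangent-space principal components of aligned coordinates.

    ``scores`` (n, m) are projections of the centered flattened coordinates
    on the ``loadings`` (m, 2k), which are orthonormal; ``eigenvalues`` are
    the corresponding sample variances (non-increasing) and sum to the total
    coordinate variance.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray
    mean: np.ndarray  # (2k,) mean flattened aligned coordinates

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def score(self, i: int) -> np.ndarray:
        """Scores of 1-based component ``i``."""
        return self.scores[:, i - 1]


def tangent_pca(shapes: AlignedShapeSet) -> ShapePCA:
    """PCA of the Procrustes-aligned coordinates (covariance, not correlation).

    Keeps ``min(n - 1, 2k)`` components. The sign of each loading is fixed so
    its largest-magnitude element is positive.
    """
    if shapes.n < 3:
        raise ValueError("tangent PCA needs at least 3 specimens")
    X = shapes.flat()
    mean = X.mean(axis=0)
    Xc = X - mean
    n = Xc.shape[0]
    m = min(n - 1, Xc.shape[1])
    # SVD route: eigenvalues of the covariance are s^2 / (n - 1)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = (s**2) / (n - 1)
    loadings = vt[:m]
    eigvals = eigvals[:m]
    # deterministic sign: largest-|.| element of each loading positive
    idx = np.argmax(np.abs(loadings), axis=1)
    signs = np.sign(loadings[np.arange(m), idx])
    signs[signs == 0] = 1.0
    loadings = loadings * signs[:, None]
    scores = Xc @ loadings.T
    total = float(Xc.var(axis=0, ddof=1).sum())
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return ShapePCA(
        scores=scores,
        eigenvalues=eigvals,
        loadings=loadings,
        variance_fractions=fractions,
        mean=mean,
    )


@dataclass
class AllometryModel:
    """Static allometry: per-coordinate linear response to centroid size.

    ``intercepts`` + ``slopes``·size predicts each of the 2k flattened
    Procrustes coordinates.  ``cac`` is the common allometric component: the
    unit vector of covariances between centered coordinates and centroid
    size, or None when the shape-size covariance is numerically zero.
    """

    intercepts: np.ndarray
    slopes: np.ndarray
    cac: Optional[np.ndarray]
    size_range: tuple

    @property
    def k(self) -> int:
        return self.slopes.size // 2

    def predict(self, sizes: np.ndarray) -> np.ndarray:
        """Predicted flattened shapes, one row per size."""
        sizes = np.atleast_1d(np.asarray(sizes, float))
        return self.intercepts[None, :] + sizes[:, None] * self.slopes[None, :]


def fit_allometry(shapes: AlignedShapeSet) -> AllometryModel:
    """Least-squares fit of every aligned coordinate on raw centroid size."""
    if shapes.n < 3:
        raise ValueError("allometry fit needs at least 3 specimens")
    sizes = shapes.centroid_sizes
    if np.ptp(sizes) <= 0:
        raise ValueError("centroid size is constant: allometry is undefined")
    X = shapes.flat()
    s = sizes - sizes.mean()
    denom = float(s @ s)
    cov = (X - X.mean(axis=0)).T @ s / (len(s) - 1)
    slopes = (X - X.mean(axis=0)).T @ s / denom
    intercepts = X.mean(axis=0) - slopes * sizes.mean()
    norm = float(np.linalg.norm(cov))
    cac = cov / norm if norm > 1e-12 else None
    return AllometryModel(
        intercepts=intercepts,
        slopes=slopes,
        cac=cac,
        size_range=(float(sizes.min()), float(sizes.max())),
    )
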