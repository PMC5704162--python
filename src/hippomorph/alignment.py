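"""Procrustes superimposition of regularized contours.

Generalized Procrustes analysis (GPA) removes the nuisance similarity
transform — location, size, and orientation — from every shape before
statistical modelling, leaving pure shape variation.  Each shape is centred
and fixed at unit centroid size (root-mean-square distance of its points to
their centroid equals 1) and then iteratively rotated into the evolving mean
until the mean stabilizes.  Scale is removed deliberately: overall head size
is a known confounder of single-slice hippocampal measurements, so group
differences are expressed through shape alone.

Reflections are never part of the fitted transform (rotation determinant is
forced to +1); the two hippocampal sides are modelled separately, and an
explicit :func:`mirror_shape` utility exists for callers who want to pool
mirrored sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .resampling import ShapeVector

__all__ = [
    "AlignedSet",
    "ProcrustesAlignment",
    "align_pair",
    "generalized_procrustes",
    "mirror_shape",
]


def _to_points(shape) -> np.ndarray:
    if isinstance(shape, ShapeVector):
        return shape.points().copy()
    return np.asarray(shape, dtype=float).reshape(-1, 2).copy()


def centroid_size(points: np.ndarray) -> float:
    """Root-mean-squared distance of the points to their centroid."""
    centred = points - points.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def _optimal_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (det +1) maximizing tr(R @ moving.T @ target)."""
    h = moving.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, d]) @ u.T


def _rotation_angle(r: np.ndarray) -> float:
    return float(np.arctan2(r[1, 0], r[0, 0]))


def _canonical_gauge(mean_pts: np.ndarray) -> np.ndarray:
    """Rotation bringing a mean shape into its canonical principal frame.

    The major principal axis of the point scatter is rotated onto x; the
    remaining 180-degree ambiguity is resolved by the sign of the third
    moment along x (falling back to y when the shape is x-symmetric).
    Because the construction uses only the shape itself, the fitted frame is
    invariant to any common similarity transform applied to the inputs.
    """
    c = mean_pts.T @ mean_pts
    _, evecs = np.linalg.eigh(c)
    r = evecs[:, ::-1].T  # rows: major, then minor axis
    if np.linalg.det(r) < 0:
        r[1] *= -1.0
    pts = mean_pts @ r.T
    sx = float(np.sum(pts[:, 0] ** 3))
    sy = float(np.sum(pts[:, 1] ** 3))
    flip = sx < 0 if abs(sx) > 1e-9 else sy < 0
    if flip:
        r = -r  # rotate by 180 degrees (still a proper rotation in 2D)
    return r


def align_pair(moving, target):
    """Least-squares similarity superimposition of one shape onto another.

    Finds the translation, scale and (proper) rotation minimizing the sum of
    squared distances between corresponding points, via the closed-form
    orthogonal-Procrustes solution.

    Returns
    -------
    aligned : same type as ``moving``
        The transformed shape.
    transform : dict
        ``translation`` (2-vector, applied after rotation/scale), ``scale``
        (positive float), ``rotation`` (radians, CCW).
    """
    p = _to_points(moving)
    q = _to_points(target)
    if p.shape != q.shape:
        raise ValueError(f"shape size mismatch: {p.shape} vs {q.shape}")
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    pc, qc = p - cp, q - cq
    norm_p = np.linalg.norm(pc)
    if norm_p == 0 or np.linalg.norm(qc) == 0:
        raise ValueError("degenerate shape: all points coincide")
    r = _optimal_rotation(pc, qc)
    # full-Procrustes scale: projection of the rotated moving shape onto target
    scale = float(np.trace(r @ pc.T @ qc) / (norm_p**2))
    aligned_pts = scale * pc @ r.T + cq
    transform = {
        "translation": cq - scale * (r @ cp),
        "scale": scale,
        "rotation": _rotation_angle(r),
    }
    if isinstance(moving, ShapeVector):
        aligned = ShapeVector(aligned_pts.ravel(), moving.n_points, moving.fiducial_slots)
    else:
        aligned = aligned_pts.ravel() if np.asarray(moving).ndim == 1 else aligned_pts
    return aligned, transform


@dataclass
class AlignedSet:
    """Result of generalized Procrustes alignment.

    ``shapes`` is the (n, 2N) matrix of aligned shape vectors, each with
    centroid at the origin and unit centroid size; ``mean_shape`` is their
    renormalized arithmetic mean.  ``transforms`` records, per input shape,
    the removed translation (its original centroid, mm), scale (its original
    centroid size) and the applied rotation (radians).
    """

    shapes: np.ndarray
    mean_shape: np.ndarray
    transforms: list
    iterations: int
    converged: bool
    ssd_history: list = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return self.mean_shape.size // 2


def generalized_procrustes(shapes, tol: float = 1e-10, max_iter: int = 100) -> AlignedSet:
    """Iterative least-squares superimposition of a set of shapes.

    Shapes are centred and fixed at unit centroid size, then repeatedly
    rotated into the current mean; the mean is recomputed and renormalized
    until it moves by less than ``tol`` (Frobenius norm) or ``max_iter`` is
    reached.  The rotational gauge is fixed by rotating the converged
    constellation into the mean shape's canonical principal-axis frame,
    which makes the result invariant to any common similarity transform of
    the inputs.
    """
    pts = [_to_points(s) for s in shapes]
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 shapes")
    if any(p.shape != pts[0].shape for p in pts):
        raise ValueError("all shapes must share the same number of points")
    centroids = [p.mean(axis=0) for p in pts]
    sizes = [centroid_size(p) for p in pts]
    if any(s == 0 for s in sizes):
        raise ValueError("degenerate shape: all points coincide")
    unit = [(p - c) / s for p, c, s in zip(pts, centroids, sizes)]

    mean = unit[0].copy()
    rotations = [np.eye(2) for _ in range(n)]
    aligned = [u.copy() for u in unit]
    ssd_history = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        rotations = [_optimal_rotation(u, mean) for u in unit]
        aligned = [u @ r.T for u, r in zip(unit, rotations)]
        new_mean = np.mean(aligned, axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= centroid_size(new_mean)
        delta = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        ssd_history.append(float(sum(np.sum((a - mean) ** 2) for a in aligned)))
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"generalized Procrustes did not converge in {max_iter} iterations",
            stacklevel=2,
        )

    # final pass against the converged mean, so every aligned shape is the
    # exact rotation-only superimposition onto the reported mean
    rotations = [_optimal_rotation(u, mean) for u in unit]
    aligned = [u @ r.T for u, r in zip(unit, rotations)]

    # canonical principal-axis gauge (invariant to common input transforms)
    gauge = _canonical_gauge(mean)
    mean = mean @ gauge.T
    aligned = [a @ gauge.T for a in aligned]
    rotations = [gauge @ r for r in rotations]

    transforms = [
        {"translation": c, "scale": s, "rotation": _rotation_angle(r)}
        for c, s, r in zip(centroids, sizes, rotations)
    ]
    return AlignedSet(
        shapes=np.asarray([a.ravel() for a in aligned]),
        mean_shape=mean.ravel(),
        transforms=transforms,
        iterations=iterations,
        converged=converged,
        ssd_history=ssd_history,
    )


def mirror_shape(shape):
    """Mirror a shape about the y-axis, restoring CCW traversal.

    Off the default pipeline path: sides are modelled separately, but this
    utility lets callers pool mirrored left/right shapes in a common frame.
    """
    pts = _to_points(shape)
    pts[:, 0] = -pts[:, 0]
    n = len(pts)
    pts = pts[[0] + list(range(n - 1, 0, -1))]
    if isinstance(shape, ShapeVector):
        slots = tuple(sorted((shape.n_points - s) % shape.n_points for s in shape.fiducial_slots))
        return ShapeVector(pts.ravel(), shape.n_points, slots)
    return pts.ravel() if np.asarray(shape).ndim == 1 else pts


class ProcrustesAlignment(BaseEstimator, TransformerMixin):
    """Generalized Procrustes alignment as a scikit-learn transformer.

    ``fit`` runs GPA on a stacked (n_samples, 2N) shape-vector matrix;
    ``transform`` superimposes (new) shapes onto the fitted mean by
    centring, scaling to unit centroid size and rotating — the same
    normalization the training set received.

    Parameters
    ----------
    tol : float
        Mean-shape convergence threshold (Frobenius norm between iterations).
    max_iter : int
        Iteration cap; non-convergence produces a warning, not an error.
    tangent_projection : bool
        If True, ``transform`` additionally rescales each aligned shape onto
        the tangent hyperplane at the mean (off by default; the pipeline
        models raw aligned coordinates).

    Attributes
    ----------
    mean_shape_ : (2N,) ndarray
    aligned_ : (n_samples, 2N) ndarray — the aligned training set.
    transforms_ : list of dict — removed similarity parameters per shape.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100, tangent_projection: bool = False):
        self.tol = tol
        self.max_iter = max_iter
        self.tangent_projection = tangent_projection

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        result = generalized_procrustes(X, tol=self.tol, max_iter=self.max_iter)
        self.mean_shape_ = result.mean_shape
        self.aligned_ = result.shapes
        self.transforms_ = result.transforms
        self.n_iter_ = result.iterations
        self.converged_ = result.converged
        self.ssd_history_ = result.ssd_history
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_shape_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mean_pts = self.mean_shape_.reshape(-1, 2)
        out = np.empty_like(X)
        for i, row in enumerate(X):
            p = row.reshape(-1, 2)
            p = p - p.mean(axis=0)
            size = centroid_size(p)
            if size == 0:
                raise ValueError("degenerate shape: all points coincide")
            p /= size
            r = _optimal_rotation(p, mean_pts)
            a = p @ r.T
            if self.tangent_projection:
                a = a * (np.sum(mean_pts**2) / np.sum(a * mean_pts))
            out[i] = a.ravel()
        return out

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X)
        return self.aligned_
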