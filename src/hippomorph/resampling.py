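"""Contour regularization: periodic splines and arc-length resampling.

Hand-drawn outlines are sampled unevenly and with different point counts, so
raw vertices cannot serve as corresponding landmarks.  Each contour is first
fitted with a closed (periodic) interpolating cubic spline; the curve is then
re-parameterized by arc length and resampled into a fixed number ``N`` of
control points anchored at the anatomical fiducials.  Within each fiducial
segment the points are equally spaced in arc length; the segment point budget
(the ``fiducial_slots``) is fixed once per cohort so that slot *i* refers to
the same anatomical locus in every shape — this is what gives the downstream
point-distribution model its point-to-point correspondence.

The regularized contour is flattened into the shape vector
``[x1, y1, x2, y2, ..., xN, yN]`` used by the alignment and modelling stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import CubicSpline, PchipInterpolator

from .io import Cohort, ContourReading

__all__ = [
    "PeriodicSpline",
    "ShapeVector",
    "fit_spline",
    "resample_contour",
    "resample_cohort",
    "default_fiducial_slots",
    "vectorize",
    "devectorize",
]


@dataclass
class ShapeVector:
    """A regularized contour as an interleaved coordinate vector.

    ``coords`` has length ``2 * n_points`` ordered ``[x1, y1, ..., xN, yN]``.
    ``fiducial_slots`` are the indices (into the N regularized points) that
    coincide with the anatomical fiducials; they are identical for every
    shape in a cohort.
    """

    coords: np.ndarray
    n_points: int
    fiducial_slots: tuple

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).ravel()
        if self.coords.size != 2 * self.n_points:
            raise ValueError(
                f"coords length {self.coords.size} != 2 * n_points ({self.n_points})"
            )
        self.fiducial_slots = tuple(int(s) for s in self.fiducial_slots)

    def points(self) -> np.ndarray:
        """Return the (N, 2) point array."""
        return self.coords.reshape(-1, 2)


def vectorize(points, fiducial_slots=()) -> ShapeVector:
    """Flatten (N, 2) points into the interleaved shape vector."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (N, 2)")
    return ShapeVector(pts.ravel(), len(pts), tuple(fiducial_slots))


def devectorize(shape) -> np.ndarray:
    """Inverse of :func:`vectorize`: recover the (N, 2) point array."""
    coords = shape.coords if isinstance(shape, ShapeVector) else np.asarray(shape)
    return np.asarray(coords, dtype=float).reshape(-1, 2)


def _dedup_points(points: np.ndarray, tol: float = 1e-12):
    """Collapse consecutive duplicate vertices (and a duplicated wrap point).

    Returns the deduplicated array and a map from original vertex index to
    its index in the deduplicated array.
    """
    pts = np.asarray(points, dtype=float)
    keep = [0]
    index_map = np.zeros(len(pts), dtype=int)
    for i in range(1, len(pts)):
        if np.linalg.norm(pts[i] - pts[keep[-1]]) <= tol:
            index_map[i] = len(keep) - 1
        else:
            index_map[i] = len(keep)
            keep.append(i)
    out = pts[keep]
    # wrap-around duplicate: last point equal to the first
    if len(out) > 1 and np.linalg.norm(out[-1] - out[0]) <= tol:
        index_map[index_map == len(out) - 1] = 0
        out = out[:-1]
    if len(out) < len(pts):
        warnings.warn(
            f"collapsed {len(pts) - len(out)} duplicate contour point(s)",
            stacklevel=3,
        )
    return out, index_map


class PeriodicSpline:
    """Closed C2 interpolating cubic spline with an arc-length parameterization.

    The spline interpolates the given vertices (chord-length knot parameter,
    periodic end conditions).  Arc length is accumulated by per-subinterval
    Gauss–Legendre quadrature of the spline speed on a fine grid and inverted
    through a monotone interpolant refined with Newton steps, giving
    ``point_at_arclength`` accuracy near machine precision.
    """

    _GL_NODES, _GL_WEIGHTS = leggauss(8)

    def __init__(self, points, subdivisions_per_segment: int = 30):
        pts, index_map = _dedup_points(points)
        if len(pts) < 4:
            raise ValueError(f"need at least 4 distinct points, got {len(pts)}")
        self._index_map = index_map
        closed = np.vstack([pts, pts[:1]])
        chord = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        knots = np.concatenate([[0.0], np.cumsum(chord)])
        self.knots = knots
        self._spline = CubicSpline(knots, closed, bc_type="periodic", axis=0)
        self._deriv = self._spline.derivative()
        self._t_max = knots[-1]

        # fine grid for cumulative arc length
        m = subdivisions_per_segment
        t_fine = np.concatenate(
            [np.linspace(knots[i], knots[i + 1], m + 1)[:-1] for i in range(len(chord))]
            + [[self._t_max]]
        )
        a, b = t_fine[:-1], t_fine[1:]
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        nodes = mid[None, :] + half[None, :] * self._GL_NODES[:, None]
        speeds = np.linalg.norm(self._deriv(nodes.ravel()), axis=1).reshape(nodes.shape)
        seg_len = half * (self._GL_WEIGHTS[:, None] * speeds).sum(axis=0)
        s_fine = np.concatenate([[0.0], np.cumsum(seg_len)])
        self._t_fine = t_fine
        self._s_fine = s_fine
        self.total_length = float(s_fine[-1])
        # arc length at the original knots (every knot is a fine-grid edge)
        self.knot_arclengths = s_fine[np.arange(len(knots)) * m]
        self._t_of_s = PchipInterpolator(s_fine, t_fine)

    # -- parameter-domain queries ----------------------------------------

    def position(self, t):
        """Curve position at parameter ``t`` (wrapped periodically)."""
        return self._spline(np.mod(t, self._t_max))

    def speed(self, t):
        return np.linalg.norm(
            np.atleast_2d(self._deriv(np.mod(t, self._t_max))), axis=-1
        )

    def arclength(self, t):
        """Exact-quadrature cumulative arc length from the curve start to ``t``."""
        t = np.atleast_1d(np.mod(t, self._t_max))
        j = np.clip(np.searchsorted(self._t_fine, t, side="right") - 1, 0, None)
        a = self._t_fine[j]
        half = 0.5 * (t - a)
        mid = 0.5 * (t + a)
        nodes = mid[None, :] + half[None, :] * self._GL_NODES[:, None]
        speeds = np.linalg.norm(self._deriv(nodes.ravel()), axis=1).reshape(nodes.shape)
        return self._s_fine[j] + half * (self._GL_WEIGHTS[:, None] * speeds).sum(axis=0)

    # -- arc-length-domain queries ----------------------------------------

    def t_at_arclength(self, s):
        """Invert the arc-length function (vectorized, Newton-refined)."""
        s = np.atleast_1d(np.mod(s, self.total_length))
        t = np.asarray(self._t_of_s(s), dtype=float)
        for _ in range(2):
            resid = self.arclength(t) - s
            t = t - resid / np.maximum(self.speed(t), 1e-300)
            t = np.clip(t, 0.0, self._t_max)
        return t

    def point_at_arclength(self, s):
        return self.position(self.t_at_arclength(s))

    def knot_index(self, original_vertex_index: int) -> int:
        """Map a vertex index of the input polyline to its spline knot index."""
        return int(self._index_map[original_vertex_index])


def fit_spline(reading: ContourReading) -> PeriodicSpline:
    """Fit the closed interpolating cubic spline through a reading's vertices."""
    return PeriodicSpline(reading.points)


def resample_contour(
    reading: ContourReading, n_points: int, fiducial_slots
) -> ShapeVector:
    """Resample a contour into ``n_points`` arc-length-regular control points.

    The output point at each fiducial slot coincides with the spline position
    of the corresponding input fiducial; between consecutive fiducials the
    points are equally spaced in arc length.  Traversal starts at fiducial 0
    and follows the contour's (CCW) orientation.

    Parameters
    ----------
    n_points : int
        Number of regularized control points N (N >= K + 2).
    fiducial_slots : sequence of K ints
        Output indices reserved for the fiducials; strictly increasing,
        first slot must be 0, all < ``n_points``.  Must be shared by every
        shape of a cohort.
    """
    slots = tuple(int(s) for s in fiducial_slots)
    k = len(reading.fiducial_indices)
    if len(slots) != k:
        raise ValueError(f"{len(slots)} slots for {k} fiducials")
    if n_points < k + 2:
        raise ValueError(f"n_points={n_points} must be >= K + 2 = {k + 2}")
    if slots[0] != 0:
        raise ValueError("first fiducial slot must be 0")
    if any(b - a < 1 for a, b in zip(slots, slots[1:])) or slots[-1] >= n_points:
        raise ValueError(f"fiducial slots {slots} infeasible for N={n_points}")

    spline = fit_spline(reading)
    length = spline.total_length
    s_fid = np.array(
        [spline.knot_arclengths[spline.knot_index(i)] for i in reading.fiducial_indices]
    )
    counts = np.diff(np.concatenate([slots, [n_points]]))
    s_values = []
    for j in range(k):
        s_start = s_fid[j]
        s_end = s_fid[(j + 1) % k]
        seg = (s_end - s_start) % length
        if seg == 0.0:  # single fiducial: the segment is the whole contour
            seg = length
        s_values.append(s_start + seg * np.arange(counts[j]) / counts[j])
    s_values = np.concatenate(s_values)
    pts = spline.point_at_arclength(s_values)
    return ShapeVector(pts.ravel(), n_points, slots)


def default_fiducial_slots(cohort: Cohort, n_points: int):
    """Fiducial slot assignment from the cohort-mean arc-length fractions.

    For each reading, the cumulative arc-length fraction of each fiducial
    (measured from fiducial 0) is computed; slot *k* is placed at
    ``round(N * mean_fraction_k)``.  The result is repaired, if necessary, to
    be strictly increasing with slot 0 at index 0, then frozen for the cohort.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    k = len(cohort.readings[0].fiducial_indices)
    fractions = np.zeros((len(cohort), k))
    for row, reading in enumerate(cohort):
        spline = fit_spline(reading)
        s = np.array(
            [
                spline.knot_arclengths[spline.knot_index(i)]
                for i in reading.fiducial_indices
            ]
        )
        fractions[row] = np.mod(s - s[0], spline.total_length) / spline.total_length
    mean_frac = fractions.mean(axis=0)
    slots = np.round(n_points * mean_frac).astype(int)
    slots[0] = 0
    for j in range(1, k):  # repair monotonicity and tail room
        slots[j] = max(slots[j], slots[j - 1] + 1)
    for j in range(k - 1, 0, -1):
        slots[j] = min(slots[j], n_points - (k - j))
    if any(b - a < 1 for a, b in zip(slots, slots[1:])) or slots[-1] >= n_points:
        raise ValueError(f"cannot place {k} fiducials into {n_points} slots")
    return tuple(int(s) for s in slots)


def resample_cohort(
    cohort: Cohort, n_points: int = 20, fiducial_slots=None
):
    """Regularize every reading of a cohort into shape vectors.

    Returns ``(X, meta, fiducial_slots)`` where ``X`` is the (n_readings, 2N)
    stacked shape-vector matrix and ``meta`` a DataFrame with one provenance
    row (subject_id, side, group, reader_id, repeat_index) per matrix row.
    """
    if fiducial_slots is None:
        fiducial_slots = default_fiducial_slots(cohort, n_points)
    rows = []
    meta = []
    for reading in cohort:
        sv = resample_contour(reading, n_points, fiducial_slots)
        rows.append(sv.coords)
        meta.append(
            {
                "subject_id": reading.subject_id,
                "side": reading.side,
                "group": reading.group,
                "reader_id": reading.reader_id,
                "repeat_index": reading.repeat_index,
            }
        )
    X = np.asarray(rows)
    return X, pd.DataFrame(meta), tuple(fiducial_slots)
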