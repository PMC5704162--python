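"""Point-distribution shape model: Karhunen–Loeve expansion of aligned contours.

After Procrustes alignment, the cohort of shape vectors is decomposed about
its mean into orthonormal modes of variation (a PCA of the landmark
covariance).  Any shape x in the aligned frame is then

    x = x_mean + P b,

where the columns of P are the eigenvectors of the sample covariance and the
shape parameters b are the mode coefficients.  Truncating to the leading M
modes (chosen by cumulative explained variance) yields a compact generative
model: shapes synthesized from parameters within a few standard deviations
resemble legal anatomy, and the parameters themselves are the features fed to
the classifier.

The decomposition is computed through the singular values of the centred
data matrix rather than by forming the covariance — numerically preferable
when 2N exceeds the sample count — with eigenvector signs fixed so the
largest-magnitude component of each mode is positive (reproducible parameter
signs across platforms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .alignment import AlignedSet

__all__ = [
    "PointDistributionModel",
    "ShapeParameters",
    "fit_model",
    "choose_modes",
    "project",
    "synthesize",
    "mahalanobis",
]

#: modes with eigenvalue below this fraction of the leading eigenvalue are
#: treated as numerically null (excluded from Mahalanobis distances).
NULL_MODE_RTOL = 1e-12


@dataclass
class ShapeParameters:
    """Mode coefficients of one shape under a fitted model."""

    b: np.ndarray
    model_ref: "PointDistributionModel"
    M: int

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.b.size != self.M:
            raise ValueError("parameter vector length must equal M")


class PointDistributionModel(BaseEstimator, TransformerMixin):
    """PCA shape model over aligned shape vectors (scikit-learn transformer).

    Parameters
    ----------
    n_modes : int or None
        Number of modes returned by ``transform``; ``None`` keeps all
        non-null modes.  Can be overridden per call.
    side : str or None
        Optional tag recording which hippocampal side the model was built
        from (left and right are modelled separately).

    Attributes
    ----------
    mean_ : (2N,) ndarray — mean aligned shape.
    components_ : (M_full, 2N) ndarray — orthonormal modes, one per row
        (column basis = ``components_.T``), sorted by decreasing variance.
    eigenvalues_ : (M_full,) ndarray — per-mode variances (divisor n-1).
    n_samples_ : int
    """

    def __init__(self, n_modes: int | None = None, side: str | None = None):
        self.n_modes = n_modes
        self.side = side

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need an (n >= 3, 2N) matrix of aligned shapes")
        n = X.shape[0]
        self.mean_ = X.mean(axis=0)
        centred = X - self.mean_
        # SVD route: eigenvalues of the covariance are s^2 / (n - 1)
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        m_full = min(X.shape[1], n - 1)
        s, vt = s[:m_full], vt[:m_full]
        # sign convention: largest-|component| of each mode is positive
        flip = np.sign(vt[np.arange(m_full), np.argmax(np.abs(vt), axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = vt * flip[:, None]
        self.eigenvalues_ = s**2 / (n - 1)
        self.n_samples_ = n
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def m_full_(self) -> int:
        check_is_fitted(self, "components_")
        return self.components_.shape[0]

    # -- mode selection ----------------------------------------------------

    def choose_modes(self, variance_fraction: float) -> int:
        """Smallest M whose cumulative eigenvalue fraction reaches the target."""
        check_is_fitted(self, "eigenvalues_")
        if not 0 < variance_fraction <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")
        total = self.eigenvalues_.sum()
        if total == 0:
            return 1
        cum = np.cumsum(self.eigenvalues_) / total
        return int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)

    def explained_variance_ratio(self) -> np.ndarray:
        check_is_fitted(self, "eigenvalues_")
        return self.eigenvalues_ / self.eigenvalues_.sum()

    # -- projection / synthesis -------------------------------------------

    def transform(self, X, n_modes: int | None = None) -> np.ndarray:
        """Project aligned shapes onto the leading modes: b = P^T (x - mean)."""
        check_is_fitted(self, "components_")
        m = self._resolve_modes(n_modes)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean_.size:
            raise ValueError(
                f"shape dimension {X.shape[1]} does not match model ({self.mean_.size})"
            )
        return (X - self.mean_) @ self.components_[:m].T

    def inverse_transform(self, B) -> np.ndarray:
        """Synthesize shapes from mode coefficients: x = mean + P b."""
        check_is_fitted(self, "components_")
        B = np.atleast_2d(np.asarray(B, dtype=float))
        if B.shape[1] > self.m_full_:
            raise ValueError("more coefficients than model modes")
        return self.mean_ + B @ self.components_[: B.shape[1]]

    def _resolve_modes(self, n_modes: int | None) -> int:
        m = n_modes if n_modes is not None else self.n_modes
        if m is None:
            return self.m_full_
        if not 1 <= m <= self.m_full_:
            raise ValueError(f"n_modes must be in [1, {self.m_full_}]")
        return int(m)

    # -- distances ---------------------------------------------------------

    def mahalanobis(self, a, b) -> float:
        """Eigenvalue-weighted distance between two parameter vectors.

        Numerically null modes (eigenvalue < 1e-12 of the leading one) are
        excluded from the sum.
        """
        check_is_fitted(self, "eigenvalues_")
        a = np.asarray(a, dtype=float).ravel()
        b = np.asarray(b, dtype=float).ravel()
        if a.size != b.size:
            raise ValueError("parameter vectors must have equal length")
        lam = self.eigenvalues_[: a.size]
        keep = lam >= NULL_MODE_RTOL * self.eigenvalues_[0]
        diff = a[keep] - b[keep]
        return float(np.sqrt(np.sum(diff**2 / lam[keep])))

    # -- persistence --------------------------------------------------------

    def to_dict(self, **extra) -> dict:
        check_is_fitted(self, "components_")
        doc = {
            "schema_version": 1,
            "side": self.side,
            "n_samples": int(self.n_samples_),
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
        }
        doc.update(extra)
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "PointDistributionModel":
        model = cls(side=doc.get("side"))
        model.mean_ = np.asarray(doc["mean"], dtype=float)
        model.components_ = np.asarray(doc["components"], dtype=float)
        model.eigenvalues_ = np.asarray(doc["eigenvalues"], dtype=float)
        model.n_samples_ = int(doc["n_samples"])
        model.n_features_in_ = model.mean_.size
        return model

    def save(self, path, **extra) -> None:
        with open(Path(path), "w") as fh:
            json.dump(self.to_dict(**extra), fh)

    @classmethod
    def load(cls, path) -> "PointDistributionModel":
        with open(Path(path)) as fh:
            return cls.from_dict(json.load(fh))


# -- functional wrappers ---------------------------------------------------


def fit_model(aligned, side: str | None = None) -> PointDistributionModel:
    """Fit a point-distribution model from an AlignedSet (or (n, 2N) matrix)."""
    X = aligned.shapes if isinstance(aligned, AlignedSet) else np.asarray(aligned)
    return PointDistributionModel(side=side).fit(X)


def choose_modes(model: PointDistributionModel, variance_fraction: float) -> int:
    return model.choose_modes(variance_fraction)


def project(model: PointDistributionModel, shape, M: int | None = None) -> ShapeParameters:
    """Project one aligned shape into model space (first M coefficients)."""
    coords = np.asarray(getattr(shape, "coords", shape), dtype=float).ravel()
    b = model.transform(coords[None, :], n_modes=M)[0]
    return ShapeParameters(b=b, model_ref=model, M=b.size)


def synthesize(model: PointDistributionModel, params) -> np.ndarray:
    """Back-project parameters to a shape vector: mean + sum_m b_m P_m."""
    b = params.b if isinstance(params, ShapeParameters) else np.asarray(params)
    return model.inverse_transform(np.atleast_2d(b))[0]


def mahalanobis(model: PointDistributionModel, a, b) -> float:
    av = a.b if isinstance(a, ShapeParameters) else a
    bv = b.b if isinstance(b, ShapeParameters) else b
    return model.mahalanobis(av, bv)
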