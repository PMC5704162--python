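"""Two-group discrimination on shape-model parameters with a linear SVM.

The classifier consumes the first M mode coefficients of each consensus
shape and separates controls from early-AD subjects with a soft-margin
support vector machine.  The decision rule is

    f(x) = sgn( sum_i alpha_i y_i K(x_i . x) + b ),     K(s) = gamma s + beta,

with a pure linear kernel (gamma=1, beta=0) by default — the published
evaluation found no benefit in higher-order kernels for this problem.
Labels are encoded control = -1, subject = +1; a decision value of exactly 0
is mapped to the control class.

``mode_sweep`` retrains the classifier for M = 1..M_max and records the
confusion counts and metrics per M; ``select_optimum`` locates the operating
point by maximizing the mean of the ten per-class performance indices
(sensitivity, specificity, precision, accuracy, F over both class views),
breaking ties toward the smallest M (the simplest adequate model prevails).

The quadratic program behind ``fit`` is solved by scikit-learn's SVC;
training rows are canonically sorted first so results are independent of
input order, and the decision values exposed here are recomputed from the
stored support coefficients rather than delegated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .consensus import consensus_matrix
from .evaluation import (
    CONTROL,
    SUBJECT,
    ConfusionCounts,
    MetricsReport,
    confusion_from_predictions,
    metrics_report,
)

__all__ = [
    "ShapeSVC",
    "ModeSweepResult",
    "train_svm",
    "classify",
    "mode_sweep",
    "select_optimum",
]

LABEL_CODE = {CONTROL: -1, SUBJECT: +1}
CODE_LABEL = {-1: CONTROL, +1: SUBJECT}


class ShapeSVC(BaseEstimator, ClassifierMixin):
    """Soft-margin SVM with the affine kernel K(s) = gamma s + beta.

    Parameters
    ----------
    M : int or None
        Number of leading feature columns used; ``None`` uses all.
    cost : float
        Soft-margin cost C (default 1, the conventional default).
    kernel_slope, kernel_intercept : float
        gamma (> 0) and beta of the kernel; defaults give the plain linear
        kernel.
    standardize : bool
        Standardize each feature (zero mean, unit variance over the training
        set) before the kernel — the conventional default of SVM toolkits,
        and necessary here because raw mode coefficients of unit-size shapes
        are orders of magnitude smaller than the soft-margin target.
        Support vectors and decision values live in the standardized space.
    tol : float
        QP convergence tolerance.

    Attributes
    ----------
    support_vectors_ : (n_sv, M) ndarray — in standardized feature space.
    support_coefficients_ : (n_sv,) ndarray — the products alpha_i y_i.
    bias_ : float
    feature_means_, feature_scales_ : (M,) ndarrays — the standardization.
    classes_ : the two group labels, control first.
    """

    def __init__(
        self,
        M: int | None = None,
        cost: float = 1.0,
        kernel_slope: float = 1.0,
        kernel_intercept: float = 0.0,
        standardize: bool = True,
        tol: float = 1e-6,
    ):
        self.M = M
        self.cost = cost
        self.kernel_slope = kernel_slope
        self.kernel_intercept = kernel_intercept
        self.standardize = standardize
        self.tol = tol

    def _kernel(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return self.kernel_slope * (a @ b.T) + self.kernel_intercept

    def _encode(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "if":
            codes = y.astype(int)
            if not set(np.unique(codes)) <= {-1, 1}:
                raise ValueError("numeric labels must be -1 (control) / +1 (subject)")
            self._string_labels = False
            return codes
        codes = np.array([LABEL_CODE.get(str(v), 0) for v in y])
        if np.any(codes == 0):
            raise ValueError(f"labels must be {CONTROL!r}/{SUBJECT!r}")
        self._string_labels = True
        return codes

    def fit(self, X, y):
        if self.kernel_slope <= 0:
            raise ValueError("kernel_slope (gamma) must be positive")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        codes = self._encode(y)
        if len(set(codes)) < 2:
            raise ValueError("training data must contain both classes")
        m = X.shape[1] if self.M is None else int(self.M)
        if not 1 <= m <= X.shape[1]:
            raise ValueError(f"M must be in [1, {X.shape[1]}]")
        Xm = X[:, :m]
        if self.standardize:
            self.feature_means_ = Xm.mean(axis=0)
            scales = Xm.std(axis=0)
            scales[scales == 0] = 1.0
            self.feature_scales_ = scales
        else:
            self.feature_means_ = np.zeros(m)
            self.feature_scales_ = np.ones(m)
        Xm = (Xm - self.feature_means_) / self.feature_scales_
        # canonical ordering: results must not depend on presentation order
        order = np.lexsort(np.vstack([Xm.T, codes]))
        Xs, cs = Xm[order], codes[order]
        if self.kernel_slope == 1.0 and self.kernel_intercept == 0.0:
            svc = SVC(kernel="linear", C=self.cost, tol=self.tol)
        else:
            svc = SVC(kernel=self._kernel, C=self.cost, tol=self.tol)
        svc.fit(Xs, cs)
        self.support_vectors_ = Xs[svc.support_]
        # sklearn orders dual_coef_ by class; with codes sorted (-1 first)
        # dual_coef_[0] is already alpha_i * y_i for each support vector.
        self.support_coefficients_ = svc.dual_coef_[0].copy()
        self.bias_ = float(svc.intercept_[0])
        self.M_ = m
        self.classes_ = (
            np.array([CONTROL, SUBJECT]) if self._string_labels else np.array([-1, 1])
        )
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """sum_i alpha_i y_i K(x_i . x) + b, from the stored coefficients."""
        check_is_fitted(self, "support_vectors_")
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, : self.M_]
        if X.shape[1] != self.M_:
            raise ValueError(f"expected {self.M_} features, got {X.shape[1]}")
        Xs = (X - self.feature_means_) / self.feature_scales_
        return self.support_coefficients_ @ self._kernel(self.support_vectors_, Xs) + self.bias_

    def predict(self, X):
        d = self.decision_function(X)
        codes = np.where(d > 0, 1, -1)  # exactly 0 -> control by convention
        if self._string_labels:
            return np.array([CODE_LABEL[c] for c in codes])
        return codes


def train_svm(samples, labels, M: int | None = None, cost: float = 1.0) -> ShapeSVC:
    """Fit the linear-kernel SVM on the first M shape parameters."""
    X = np.asarray(
        [getattr(s, "b", s) for s in samples]
        if not isinstance(samples, np.ndarray)
        else samples,
        dtype=float,
    )
    return ShapeSVC(M=M, cost=cost).fit(X, labels)


def classify(model: ShapeSVC, x):
    """Classify a single parameter vector (or ShapeParameters)."""
    vec = np.asarray(getattr(x, "b", x), dtype=float).ravel()
    if vec.size < model.M_:
        raise ValueError(f"expected at least {model.M_} parameters, got {vec.size}")
    return model.predict(vec[None, : model.M_])[0]


@dataclass
class ModeSweepResult:
    """Per-M confusion counts and metrics plus the selected operating point."""

    rows: list  # dicts: {"M", "counts": ConfusionCounts, "report": MetricsReport}
    evaluation: str
    side: str | None = None
    optimum_M: int | None = None
    optimization_rule: str | None = None
    accuracy_curve: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the sweep: counts and metrics in the published layout."""
        records = []
        for row in self.rows:
            c: ConfusionCounts = row["counts"]
            rec = {
                "side": self.side,
                "modes": row["M"],
                "tp_c": c.tp_c,
                "tp_s": c.tp_s,
                "tn_c": c.tn_c,
                "tn_s": c.tn_s,
                "fp_c": c.fp_c,
                "fp_s": c.fp_s,
                "fn_c": c.fn_c,
                "fn_s": c.fn_s,
            }
            rec.update(row["report"].flat())
            records.append(rec)
        return pd.DataFrame(records)


def _averaged_index(report: MetricsReport) -> float:
    vals = [v for view in (report.control, report.subject) for v in view.values()]
    return float(np.mean(vals))


def mode_sweep(
    model,
    consensus,
    M_max: int,
    evaluation: str = "resubstitution",
    cost: float = 1.0,
    n_splits: int = 5,
    seed: int = 0,
    side: str | None = None,
) -> ModeSweepResult:
    """Train and evaluate the SVM for every truncation M = 1..M_max.

    ``resubstitution`` scores the classifier on its own training set — the
    original protocol, flagged here because it is optimistic — while
    ``k_fold`` pools stratified cross-validation predictions (seeded).
    """
    if evaluation not in ("resubstitution", "k_fold"):
        raise ValueError(f"unknown evaluation mode {evaluation!r}")
    B, labels, _ = consensus_matrix(consensus, side=side)
    if B.shape[0] == 0:
        raise ValueError("no consensus shapes for the requested side")
    if M_max > B.shape[1]:
        raise ValueError(f"M_max={M_max} exceeds available parameters ({B.shape[1]})")
    rows = []
    for m in range(1, M_max + 1):
        if evaluation == "resubstitution":
            clf = ShapeSVC(M=m, cost=cost).fit(B, labels)
            predicted = clf.predict(B)
        else:
            predicted = np.empty(len(labels), dtype=labels.dtype)
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            for train_idx, test_idx in skf.split(B, labels):
                clf = ShapeSVC(M=m, cost=cost).fit(B[train_idx], labels[train_idx])
                predicted[test_idx] = clf.predict(B[test_idx])
        counts = confusion_from_predictions(labels, predicted)
        rows.append({"M": m, "counts": counts, "report": metrics_report(counts)})
    result = ModeSweepResult(
        rows=rows,
        evaluation=evaluation,
        side=side,
        accuracy_curve=np.array([r["counts"].n_correct / r["counts"].n_total for r in rows]),
    )
    result.optimum_M = select_optimum(result)
    result.optimization_rule = "averaged_indices"
    return result


def select_optimum(sweep: ModeSweepResult, rule: str = "averaged_indices") -> int:
    """Pick the operating number of modes from a sweep.

    ``averaged_indices``: smallest M maximizing the mean of the ten
    per-class indices.  ``first_convergence``: smallest M whose averaged
    index is within 0.005 of the best achieved (plateau onset).
    """
    if not sweep.rows:
        raise ValueError("empty sweep")
    index = np.array([_averaged_index(r["report"]) for r in sweep.rows])
    ms = np.array([r["M"] for r in sweep.rows])
    if rule == "averaged_indices":
        return int(ms[int(np.argmax(index))])
    if rule == "first_convergence":
        good = index >= index.max() - 5e-3
        return int(ms[int(np.argmax(good))])
    raise ValueError(f"unknown rule {rule!r}")
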