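"""Classification bookkeeping and metrics in the study's reporting convention.

Counts are kept separately for two "class views": the control view (C) treats
healthy controls as the positive class, the subject view (S) treats early-AD
subjects as positive.  The reporting convention mirrors the correct counts —
TN of a view is set numerically equal to that view's TP, and FP of one view
equals FN of the other — which is the only bookkeeping under which the
published per-class sensitivity/specificity/precision/accuracy/F tables are
internally consistent.  A standard confusion-matrix convention (TN of the C
view = subjects correctly classified) is available behind a flag for
comparison with other software.

Overall metrics follow the same source: percent correct, Cohen's kappa of
the 2x2 contingency, and 0/1-loss MAE/RMSE with relative errors taken
against a prior-probability (ZeroR-style) baseline predictor.

The module also carries the conventional-metric benchmark the shape pipeline
is compared against: per-subject hippocampal formation area by trapezoidal
integration of the closed contour, per-group Gaussian fits, and the count of
subjects inside the distributions' overlap (those a Gaussian likelihood-ratio
rule misclassifies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io import Cohort

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_from_predictions",
    "cohen_kappa",
    "counts_from_row",
    "class_metrics",
    "overall_metrics",
    "metrics_report",
    "polygon_area",
    "area_benchmark",
    "load_reference_counts",
]

CONTROL, SUBJECT = "control", "subject"


@dataclass
class ConfusionCounts:
    """Two-view confusion counts (see module docstring for the convention)."""

    tp_c: int
    tp_s: int
    tn_c: int
    tn_s: int
    fp_c: int
    fp_s: int
    fn_c: int
    fn_s: int
    n_controls: int
    n_subjects: int

    def view(self, view: str) -> tuple:
        """(TP, TN, FP, FN) of one class view, ``"C"`` or ``"S"``."""
        if view == "C":
            return self.tp_c, self.tn_c, self.fp_c, self.fn_c
        if view == "S":
            return self.tp_s, self.tn_s, self.fp_s, self.fn_s
        raise ValueError(f"view must be 'C' or 'S', got {view!r}")

    @property
    def n_total(self) -> int:
        return self.n_controls + self.n_subjects

    @property
    def n_correct(self) -> int:
        return self.tp_c + self.tp_s

    def validate(self) -> "ConfusionCounts":
        for name in ("tp_c", "tp_s", "tn_c", "tn_s", "fp_c", "fp_s", "fn_c", "fn_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}")
        if self.tp_c + self.fn_c != self.n_controls:
            raise ValueError("TP_C + FN_C must equal n_controls")
        if self.tp_s + self.fn_s != self.n_subjects:
            raise ValueError("TP_S + FN_S must equal n_subjects")
        return self


def confusion_from_predictions(
    truth, predicted, convention: str = "mirrored"
) -> ConfusionCounts:
    """Tally two-view confusion counts from group labels.

    ``truth`` and ``predicted`` hold ``"control"`` / ``"subject"`` labels.
    Under the default ``mirrored`` convention TN of each view is set equal to
    its TP (the source convention); under ``standard`` TN of a view counts
    the other class's correct predictions.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    seen = set(np.unique(truth)) | set(np.unique(predicted))
    unknown = seen - {CONTROL, SUBJECT}
    if unknown:
        raise ValueError(f"unknown group labels {sorted(unknown)}")
    is_c = truth == CONTROL
    tp_c = int(np.sum(is_c & (predicted == CONTROL)))
    fn_c = int(np.sum(is_c & (predicted == SUBJECT)))
    tp_s = int(np.sum(~is_c & (predicted == SUBJECT)))
    fn_s = int(np.sum(~is_c & (predicted == CONTROL)))
    fp_c, fp_s = fn_s, fn_c  # misclassified members of the other class
    if convention == "mirrored":
        tn_c, tn_s = tp_c, tp_s
    elif convention == "standard":
        tn_c, tn_s = tp_s, tp_c
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return ConfusionCounts(
        tp_c=tp_c,
        tp_s=tp_s,
        tn_c=tn_c,
        tn_s=tn_s,
        fp_c=fp_c,
        fp_s=fp_s,
        fn_c=fn_c,
        fn_s=fn_s,
        n_controls=int(np.sum(is_c)),
        n_subjects=int(np.sum(~is_c)),
    ).validate()


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 reported as 1.0 (degenerate counts)", stacklevel=3)
        return 1.0
    return num / den


def class_metrics(counts: ConfusionCounts, view: str) -> dict:
    """Per-class-view sensitivity, specificity, precision, accuracy, F."""
    tp, tn, fp, fn = counts.view(view)
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("negative counts")
    sensitivity = _ratio(tp, tp + fn, f"sensitivity[{view}]")
    specificity = _ratio(tn, tn + fp, f"specificity[{view}]")
    precision = _ratio(tp, tp + fp, f"precision[{view}]")
    accuracy = _ratio(tp + tn, tp + tn + fp + fn, f"accuracy[{view}]")
    f_den = precision + sensitivity
    f_measure = _ratio(2 * precision * sensitivity, f_den, f"f_measure[{view}]")
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "accuracy": accuracy,
        "f_measure": f_measure,
    }


def cohen_kappa(counts: ConfusionCounts) -> float:
    """Cohen's kappa of the underlying 2x2 truth-vs-prediction contingency."""
    n = counts.n_total
    if n == 0:
        raise ValueError("empty counts")
    pred_c = counts.tp_c + counts.fn_s  # predicted control
    pred_s = counts.tp_s + counts.fn_c
    p_observed = counts.n_correct / n
    p_expected = (counts.n_controls * pred_c + counts.n_subjects * pred_s) / n**2
    if p_expected == 1.0:
        return 1.0
    return (p_observed - p_expected) / (1.0 - p_expected)


def overall_metrics(counts: ConfusionCounts) -> dict:
    """Percent correct, kappa, and 0/1-loss error statistics.

    MAE is the mean 0/1 loss (misclassified fraction) and RMSE its square
    root.  RAE and RRSE (reported in percent) normalize MAE and RMSE by a
    prior-probability baseline predictor that always outputs the training
    class frequencies (a ZeroR-style reference).
    """
    n = counts.n_total
    if n == 0:
        raise ValueError("empty counts")
    mae = (n - counts.n_correct) / n
    rmse = float(np.sqrt(mae))
    p_c = counts.n_controls / n
    p_s = counts.n_subjects / n
    baseline_mae = 2 * p_c * p_s
    baseline_rmse = float(np.sqrt(p_c * p_s**2 + p_s * p_c**2))
    return {
        "percent_correct": 100.0 * counts.n_correct / n,
        "kappa": cohen_kappa(counts),
        "mae": mae,
        "rmse": rmse,
        "rae": 100.0 * _ratio(mae, baseline_mae, "rae"),
        "rrse": 100.0 * _ratio(rmse, baseline_rmse, "rrse"),
    }


@dataclass
class MetricsReport:
    """Per-view and overall metrics for one classifier configuration."""

    control: dict
    subject: dict
    overall: dict
    counts: ConfusionCounts = None

    def flat(self) -> dict:
        row = {}
        for view, metrics in (("C", self.control), ("S", self.subject)):
            row.update({f"{k}_{view}": v for k, v in metrics.items()})
        row.update(self.overall)
        return row


def metrics_report(counts: ConfusionCounts) -> MetricsReport:
    return MetricsReport(
        control=class_metrics(counts, "C"),
        subject=class_metrics(counts, "S"),
        overall=overall_metrics(counts),
        counts=counts,
    )


# -- conventional-metric (area) benchmark ---------------------------------


def polygon_area(points) -> float:
    """Area of an implicitly-closed polygon by trapezoidal integration.

    Sums the signed trapezoids under each edge, |sum (x_{i+1}-x_i)(y_i+y_{i+1})/2|,
    algebraically identical to the shoelace formula for a closed polygon.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need an (n >= 3, 2) closed contour")
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    return float(abs(np.sum((x1 - x) * (y + y1)) / 2.0))


@dataclass
class AreaBenchmark:
    """Per-side outcome of the formation-area benchmark."""

    areas: pd.DataFrame  # subject_id, side, group, area
    gaussians: dict  # (side, group) -> (mean, sd)
    overlap_counts: dict = field(default_factory=dict)  # side -> ambiguous subjects


def area_benchmark(cohort: Cohort) -> AreaBenchmark:
    """Benchmark discrimination on hippocampal area alone.

    Per subject and side, reading areas are averaged (Cartesian mean of the
    trapezoidal polygon areas); per group a Gaussian is fitted; the overlap
    count is the number of subjects the two-Gaussian likelihood-ratio rule
    misclassifies — the "ambiguous" cases a pure area criterion cannot call.
    """
    records = []
    for r in cohort:
        records.append(
            {
                "subject_id": r.subject_id,
                "side": r.side,
                "group": r.group,
                "area": polygon_area(r.points),
            }
        )
    df = pd.DataFrame(records)
    per_subject = (
        df.groupby(["subject_id", "side", "group"], as_index=False)["area"].mean()
    )
    gaussians = {}
    overlap = {}
    for side, block in per_subject.groupby("side"):
        params = {}
        for group, rows in block.groupby("group"):
            a = rows["area"].to_numpy()
            params[group] = (float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0)
            gaussians[(side, group)] = params[group]
        if len(params) == 2:
            mu_c, sd_c = params[CONTROL]
            mu_s, sd_s = params[SUBJECT]
            sd_c, sd_s = max(sd_c, 1e-12), max(sd_s, 1e-12)
            a = block["area"].to_numpy()
            log_lr = -0.5 * ((a - mu_s) / sd_s) ** 2 - np.log(sd_s) - (
                -0.5 * ((a - mu_c) / sd_c) ** 2 - np.log(sd_c)
            )
            predicted = np.where(log_lr > 0, SUBJECT, CONTROL)
            overlap[side] = int(np.sum(predicted != block["group"].to_numpy()))
    return AreaBenchmark(areas=per_subject, gaussians=gaussians, overlap_counts=overlap)


# -- reference counts -------------------------------------------------------


def load_reference_counts() -> pd.DataFrame:
    """Published per-mode confusion counts of the original clinical evaluation.

    Columns: side, modes, tp_c, tp_s, tn_c, tn_s, fp_c, fp_s, fn_c, fn_s.
    These serve as worked-example inputs for the metric conventions.
    """
    path = resources.files("hippomorph") / "data" / "reference_confusion_counts.csv"
    with path.open() as fh:
        return pd.read_csv(fh)


def counts_from_row(row) -> ConfusionCounts:
    """Build ConfusionCounts from one reference-table row (or dict)."""
    return ConfusionCounts(
        tp_c=int(row["tp_c"]),
        tp_s=int(row["tp_s"]),
        tn_c=int(row["tn_c"]),
        tn_s=int(row["tn_s"]),
        fp_c=int(row["fp_c"]),
        fp_s=int(row["fp_s"]),
        fn_c=int(row["fn_c"]),
        fn_s=int(row["fn_s"]),
        n_controls=int(row["tp_c"]) + int(row["fn_c"]),
        n_subjects=int(row["tp_s"]) + int(row["fn_s"]),
    ).validate()
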