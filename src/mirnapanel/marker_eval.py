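"""Per-marker diagnostic validation.

For each candidate microRNA the module computes the empirical ROC curve and
trapezoid AUC, selects the operating cutoff maximizing Youden's index
J = sensitivity + specificity - 1, derives the confusion-matrix metrics at
that cutoff (sensitivity, specificity, PPV, NPV, accuracy), and fits a
univariate logistic regression reporting the odds ratio per unit of
relative expression with a Wald 95% confidence interval.

Markers come with a direction: an *up*regulated marker calls a sample
malignant when its relative expression is **above** the cutoff, a *down*-
regulated marker when it is **below**.  Internally scores of down markers
are negated so that a higher processed score always means "more malignant";
cutoffs are reported on the original expression scale.  Cutoffs are placed
at midpoints between adjacent distinct observed values, so no training
sample ever sits exactly on the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.utils.validation import check_is_fitted
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)

__all__ = [
    "RocCurve",
    "ConfusionMetrics",
    "MarkerPerformance",
    "LogisticFit",
    "roc_curve",
    "youden_cutoff",
    "confusion_metrics",
    "fit_logistic_univariate",
    "evaluate_marker",
    "YoudenClassifier",
]

# |log-odds slope| beyond which the fit is treated as (quasi-)separated.
SEPARATION_SLOPE_BOUND = 15.0


@dataclass
class RocCurve:
    """Empirical ROC curve of one marker.

    ``points`` runs from (0, 0) to (1, 1); ``thresholds`` are on the
    processed scale (scores negated for direction='down').  The original
    scores and labels ride along so that cutoff selection can revisit every
    observed operating point.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    direction: str
    scores: np.ndarray  # original scale
    labels: np.ndarray  # boolean, True = positive class

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def _processed(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction == "up":
        return scores
    if direction == "down":
        return -scores
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def roc_curve(scores, labels, direction: str = "up") -> RocCurve:
    """Empirical ROC over all distinct thresholds; AUC by the trapezoid rule.

    ``labels`` may be boolean, 0/1, or 'benign'/'malignant' strings; the
    positive class is malignant.  For ``direction='down'`` scores are
    negated before thresholding.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    keep = np.isfinite(scores)
    scores, y = scores[keep], y[keep]
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    proc = _processed(scores, direction)
    fpr, tpr, thr = _sk_roc_curve(y, proc, drop_intermediate=False)
    return RocCurve(thr, fpr, tpr, float(_trapezoid_auc(fpr, tpr)),
                    direction, scores, y)


def _as_bool_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return arr == "malignant"
    return arr.astype(bool)


def _candidate_cutoffs(proc: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct processed scores, plus guards
    below the minimum (everything positive) and above the maximum
    (everything negative)."""
    u = np.unique(proc)
    if u.size == 1:
        step = 1.0
        return np.array([u[0] - step, u[0] + step])
    mids = (u[:-1] + u[1:]) / 2.0
    step = float(np.mean(np.diff(u))) / 2.0
    return np.concatenate([[u[0] - step], mids, [u[-1] + step]])


def youden_cutoff(curve: RocCurve) -> tuple[float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Ties are broken by higher specificity, then by the lower cutoff on the
    processed scale.  The returned cutoff is on the original expression
    scale, at the midpoint between the adjacent distinct observed values.
    """
    proc = _processed(curve.scores, curve.direction)
    y = curve.labels
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best = None
    for c in _candidate_cutoffs(proc):
        pred = proc > c
        sens = float((pred & y).sum()) / n_pos
        spec = float((~pred & ~y).sum()) / n_neg
        j = sens + spec - 1.0
        key = (-j, -spec, c)
        if best is None or key < best[0]:
            best = (key, c, j)
    _, cutoff_proc, j = best
    cutoff = cutoff_proc if curve.direction == "up" else -cutoff_proc
    return float(cutoff), float(j)


@dataclass(frozen=True)
class ConfusionMetrics:
    """The five headline proportions; NaN where a denominator is zero."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy from counts."""
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return ConfusionMetrics(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        accuracy=ratio(tp + tn, tp + fp + fn + tn),
    )


@dataclass
class MarkerPerformance:
    """Full diagnostic summary of one marker at its Youden cutoff."""

    assay_id: str
    direction: str
    cutoff: float
    youden_j: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    auc: float


@dataclass
class LogisticFit:
    """Univariate logistic regression summary (odds of malignancy)."""

    intercept: float
    slope: float
    or_per_unit: float
    ci95: tuple[float, float]
    p_wald: float
    converged: bool
    separation_flag: bool


def fit_logistic_univariate(x, labels, per_log2_unit: bool = False) -> LogisticFit:
    """Maximum-likelihood logistic fit of malignancy on one marker.

    The odds ratio is per unit of relative expression by default;
    ``per_log2_unit=True`` fits on the log2 scale instead (one OR per
    doubling).  Wald 95% CI = exp(slope +- 1.96 * SE).  Complete or quasi-
    complete separation is flagged and the fit marked non-converged.
    """
    x = np.asarray(x, dtype=float)
    y = _as_bool_labels(labels).astype(float)
    if x.shape != y.shape:
        raise ValueError("x and labels must have equal length")
    if not np.isfinite(x).all():
        raise ValueError("marker values must be finite")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if per_log2_unit:
        if (x <= 0).any():
            raise ValueError("log2 scale requires strictly positive values")
        x = np.log2(x)

    X = sm.add_constant(x)
    separated = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            result = sm.Logit(y, X).fit(disp=0, maxiter=100)
            intercept, slope = map(float, result.params)
            se = float(result.bse[1])
            p_wald = float(result.pvalues[1])
            converged = bool(result.mle_retvals.get("converged", True))
        except Exception:
            separated = True
            intercept = slope = se = p_wald = float("nan")
            converged = False
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        separated = True
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        converged = False
    if np.isfinite(slope) and abs(slope) > SEPARATION_SLOPE_BOUND:
        separated = True
    if separated:
        converged = False

    # under separation the slope diverges: the CI is legitimately unbounded
    with np.errstate(over="ignore"):
        if np.isfinite(slope) and np.isfinite(se):
            ci = (float(np.exp(slope - 1.96 * se)), float(np.exp(slope + 1.96 * se)))
        else:
            ci = (float("nan"), float("nan"))
        or_unit = float(np.exp(slope)) if np.isfinite(slope) else float("nan")
    return LogisticFit(intercept, slope, or_unit, ci, p_wald, converged, separated)


def evaluate_marker(assay_id: str, values, labels, direction: str) -> MarkerPerformance:
    """ROC + Youden cutoff + confusion metrics for one marker.

    Missing values (NaN) are dropped pairwise before evaluation.
    """
    values = np.asarray(values, dtype=float)
    y = _as_bool_labels(labels)
    keep = np.isfinite(values)
    values, y = values[keep], y[keep]
    curve = roc_curve(values, y, direction)
    cutoff, j = youden_cutoff(curve)
    pred = values > cutoff if direction == "up" else values < cutoff
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    m = confusion_metrics(tp, fp, fn, tn)
    return MarkerPerformance(assay_id, direction, cutoff, j, tp, fp, fn, tn,
                             m.sensitivity, m.specificity, m.ppv, m.npv,
                             m.accuracy, curve.auc)


class YoudenClassifier(BaseEstimator, ClassifierMixin):
    """Single-marker threshold classifier at the Youden-optimal cutoff.

    ``fit(X, y)`` takes a single column of marker values; ``direction`` may
    be ``'up'``, ``'down'`` or ``'auto'`` (pick whichever direction yields
    AUC >= 0.5 on the training data).  ``predict`` returns 1 for samples
    called malignant.

    Attributes
    ----------
    cutoff_, direction_, youden_j_, auc_ : fitted operating point
    performance_ : MarkerPerformance with the in-sample confusion metrics
    """

    def __init__(self, direction: str = "auto", assay_id: str = "marker"):
        self.direction = direction
        self.assay_id = assay_id

    @staticmethod
    def _column(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2:
            if arr.shape[1] != 1:
                raise ValueError("YoudenClassifier handles exactly one marker")
            arr = arr[:, 0]
        return arr

    def fit(self, X, y) -> "YoudenClassifier":
        x = self._column(X)
        yb = _as_bool_labels(y)
        direction = self.direction
        if direction == "auto":
            direction = "up" if roc_curve(x, yb, "up").auc >= 0.5 else "down"
        perf = evaluate_marker(self.assay_id, x, yb, direction)
        self.direction_ = direction
        self.cutoff_ = perf.cutoff
        self.youden_j_ = perf.youden_j
        self.auc_ = perf.auc
        self.performance_ = perf
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoff_")
        x = self._column(X)
        return x - self.cutoff_ if self.direction_ == "up" else self.cutoff_ - x

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def performance_table(performances) -> pd.DataFrame:
    """Assemble per-marker results into the usual publication layout."""
    return pd.DataFrame([vars(p) for p in performances]).set_index("assay_id")
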