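"""Multi-marker k-of-n voting panel.

Each marker votes on each sample: an upregulated marker votes positive when
the sample's relative expression lies strictly above its cutoff, a
downregulated marker when strictly below.  A sample is called malignant
when at least ``k`` of the ``n`` markers vote positive.  Sweeping k from 1
to n traces out the panel's operating points; sensitivity can only fall
and specificity only rise as k grows, because the set of panel-positive
samples shrinks monotonically.

Two AUCs are reported deliberately:

* the **binary-rule AUC** of the chosen k — the trapezoid area of the
  two-point ROC {(0,0), (1-spec, sens), (1,1)}, i.e. (sens + spec) / 2;
* the **vote-count AUC** — the full ROC over the integer vote count as an
  ordinal score.

Neither dominates the other in general, so both are kept.

Missing marker values cast no positive vote; the number of missing calls
per sample is reported alongside so downstream QC can exclude samples with
too few informative markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .marker_eval import (
    MarkerPerformance,
    _as_bool_labels,
    confusion_metrics,
    evaluate_marker,
    roc_curve,
)

__all__ = [
    "PanelMarker",
    "PanelRule",
    "PanelPerformance",
    "call_positivity",
    "vote_count",
    "binary_rule_auc",
    "evaluate_k_of_n",
    "KofNVotingClassifier",
]


@dataclass(frozen=True)
class PanelMarker:
    """One marker of the panel: assay, cutoff, and regulation direction."""

    assay_id: str
    cutoff: float
    direction: str  # up | down

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")


@dataclass
class PanelRule:
    """A marker set plus the minimum number of positive votes."""

    markers: list[PanelMarker]
    k_min_positive: int

    def __post_init__(self) -> None:
        if not 1 <= self.k_min_positive <= len(self.markers):
            raise ValueError("k_min_positive must be in [1, n_markers]")

    @classmethod
    def from_performances(cls, performances: Sequence[MarkerPerformance],
                          k_min_positive: int) -> "PanelRule":
        markers = [PanelMarker(p.assay_id, p.cutoff, p.direction)
                   for p in performances]
        return cls(markers, k_min_positive)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.markers])


@dataclass
class PanelPerformance:
    """Per-k sweep of the voting rule plus the vote-count ROC AUC."""

    per_k: pd.DataFrame  # columns: k, tp, fp, fn, tn, sensitivity, ...
    vote_counts: np.ndarray
    missing_counts: np.ndarray
    best_k: int
    vote_auc: float = field(default=float("nan"))


def call_positivity(value: float, cutoff: float, direction: str) -> bool | None:
    """One marker's vote on one sample; None for a missing measurement."""
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if value is None or not np.isfinite(value):
        return None
    return value > cutoff if direction == "up" else value < cutoff


def vote_count(calls: Sequence[bool | None]) -> tuple[int, int]:
    """Count positive votes for one sample; missing calls vote negative.

    Returns ``(n_positive, n_missing)``; raises if every call is missing.
    """
    calls = list(calls)
    n_missing = sum(c is None for c in calls)
    if n_missing == len(calls):
        raise ValueError("all marker calls are missing for this sample")
    return sum(c is True for c in calls), n_missing


def binary_rule_auc(sensitivity: float, specificity: float) -> float:
    """AUC of the two-point ROC through (1 - specificity, sensitivity).

    Trapezoid area of {(0,0), (1-spec, sens), (1,1)} = (sens + spec) / 2.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return (sensitivity + specificity) / 2.0


def _votes_matrix(values: pd.DataFrame, rule: PanelRule) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (votes, missing) arrays for a marker-value DataFrame."""
    votes = np.zeros(len(values), dtype=int)
    missing = np.zeros(len(values), dtype=int)
    for marker in rule.markers:
        if marker.assay_id not in values.columns:
            raise KeyError(f"panel marker {marker.assay_id!r} absent from data")
        col = values[marker.assay_id].to_numpy(dtype=float)
        ok = np.isfinite(col)
        pos = np.where(
            marker.direction == "up", col > marker.cutoff, col < marker.cutoff)
        votes += (pos & ok).astype(int)
        missing += (~ok).astype(int)
    if (missing == len(rule.markers)).any():
        raise ValueError("at least one sample has no informative marker")
    return votes, missing


def evaluate_k_of_n(
    votes: Sequence[int],
    labels,
    n_markers: int,
    missing_counts: Sequence[int] | None = None,
) -> PanelPerformance:
    """Sweep the vote threshold k = 1..n and score each operating point.

    ``best_k`` maximizes the binary-rule AUC; ties go to the larger k (the
    stricter rule).  The full vote-count ROC AUC is reported separately.
    """
    votes = np.asarray(votes, dtype=int)
    y = _as_bool_labels(labels)
    if votes.shape != y.shape:
        raise ValueError("votes and labels must have equal length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if votes.min() < 0 or votes.max() > n_markers:
        raise ValueError("votes must lie in [0, n_markers]")

    rows = []
    for k in range(1, n_markers + 1):
        pred = votes >= k
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        fn = int((~pred & y).sum())
        tn = int((~pred & ~y).sum())
        m = confusion_metrics(tp, fp, fn, tn)
        rows.append((k, tp, fp, fn, tn, m.sensitivity, m.specificity,
                     binary_rule_auc(m.sensitivity, m.specificity)))
    per_k = pd.DataFrame(rows, columns=["k", "tp", "fp", "fn", "tn",
                                        "sensitivity", "specificity",
                                        "auc_binary"])
    # argmax with ties to the larger k
    best = per_k.loc[::-1].sort_values("auc_binary", kind="stable",
                                       ascending=False).iloc[0]
    vote_auc = roc_curve(votes.astype(float), y, "up").auc
    missing = (np.zeros_like(votes) if missing_counts is None
               else np.asarray(missing_counts, dtype=int))
    return PanelPerformance(per_k, votes, missing, int(best["k"]), vote_auc)


class KofNVotingClassifier(BaseEstimator, ClassifierMixin):
    """k-of-n voting panel as a scikit-learn classifier.

    ``fit(X, y)`` takes a samples x markers DataFrame (or array) of relative
    expression and binary labels; for each marker it learns the regulation
    direction (from the training AUC) and the Youden-optimal cutoff, then
    sweeps k.  ``k`` may be fixed at construction or left ``None`` to use
    the best-AUC k found during fitting.

    Attributes
    ----------
    rule_ : PanelRule with the learned cutoffs and directions
    marker_performances_ : list of MarkerPerformance (per-marker validation)
    panel_performance_ : PanelPerformance (the per-k sweep on training data)
    k_ : the operating vote threshold used by ``predict``
    """

    def __init__(self, k: int | None = None, directions: dict | None = None):
        self.k = k
        self.directions = directions

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"marker_{i}" for i in range(X.shape[1])])

    def fit(self, X, y) -> "KofNVotingClassifier":
        frame = self._as_frame(X)
        yb = _as_bool_labels(y)
        if frame.shape[0] != yb.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        performances = []
        for assay in frame.columns:
            col = frame[assay].to_numpy(dtype=float)
            if self.directions and assay in self.directions:
                direction = self.directions[assay]
            else:
                keep = np.isfinite(col)
                direction = ("up" if roc_curve(col[keep], yb[keep], "up").auc >= 0.5
                             else "down")
            performances.append(evaluate_marker(str(assay), col, yb, direction))
        rule = PanelRule.from_performances(performances, k_min_positive=1)
        votes, missing = _votes_matrix(frame, rule)
        perf = evaluate_k_of_n(votes, yb, len(rule.markers), missing)
        self.marker_performances_ = performances
        self.panel_performance_ = perf
        self.k_ = int(self.k) if self.k is not None else perf.best_k
        if not 1 <= self.k_ <= len(rule.markers):
            raise ValueError(f"k must be in [1, {len(rule.markers)}]")
        rule.k_min_positive = self.k_
        self.rule_ = rule
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        return self

    def vote(self, X) -> np.ndarray:
        """Per-sample positive-vote counts under the fitted rule."""
        check_is_fitted(self, "rule_")
        votes, _ = _votes_matrix(self._as_frame(X), self.rule_)
        return votes

    def decision_function(self, X) -> np.ndarray:
        return self.vote(X) - self.k_ + 0.5

    def predict(self, X) -> np.ndarray:
        return (self.vote(X) >= self.k_).astype(int)
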