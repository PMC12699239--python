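"""Per-assay differential-expression screen between malignant and benign groups.

Each assay of the relative-expression matrix is tested with a two-sided
Mann-Whitney U test and summarized by the log2 ratio of group geometric
means.  Assays passing both the significance gate (p < 0.05) and the linear
fold-change gate (FC >= 2, i.e. |log2FC| >= 1) are ranked by a combined
score

    score = -log10(p) + |log2FC|

which trades off strength of evidence against effect size on a common
dimensionless scale; everything else scores 0 and is labelled ``ns``.  The
top-k assays per direction become the validation candidates.

Benjamini-Hochberg q-values are always reported; by default they do not
gate the screen (768 assays screened at raw p < 0.05 is the conventional
discovery-card practice), but ``use_q_values=True`` switches the gate to
q < p_threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .io import RunConfig, SampleAnnotation
from .relquant import ExpressionMatrix

__all__ = [
    "DiffExprRecord",
    "mann_whitney_u",
    "group_fold_change",
    "combined_score",
    "screen_features",
    "select_top_candidates",
    "DifferentialScreen",
]

EXACT_MAX_N = 20  # pooled size up to which the exact U distribution is used


@dataclass(frozen=True)
class DiffExprRecord:
    """Screen output for one assay."""

    assay_id: str
    n_benign: int
    n_malignant: int
    log2fc: float
    u_stat: float
    p_value: float
    q_value: float
    combined_score: float
    direction: str  # up | down | ns


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is counted for the first group.

    U = number of (a, b) pairs with a > b plus half the ties.  The p-value
    uses the exact permutation distribution when the pooled size is at most
    20 and there are no ties, and the normal approximation with tie and
    continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # Every pair is a tie: U sits exactly at its null mean.
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def group_fold_change(
    values: Sequence[float] | pd.Series,
    is_malignant: Sequence[bool],
) -> float:
    """log2 ratio of geometric-mean relative expression, malignant / benign.

    Missing entries (NaN) are excluded pairwise.  Returns NaN when a group
    has no observed value (the caller flags such assays).
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(is_malignant, dtype=bool)
    if v.shape != m.shape:
        raise ValueError("values and group mask must have equal length")
    log2v = np.log2(v)
    mal = log2v[m & np.isfinite(log2v)]
    ben = log2v[~m & np.isfinite(log2v)]
    if mal.size == 0 or ben.size == 0:
        return float("nan")
    return float(mal.mean() - ben.mean())


def combined_score(
    p_value: float,
    log2fc: float,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> float:
    """-log10(p) + |log2FC| for assays passing both gates, else 0.

    The fold-change gate is FC >= fc_threshold or FC <= 1/fc_threshold,
    i.e. |log2FC| >= log2(fc_threshold).
    """
    if not 0 < p_value <= 1:
        raise ValueError(f"p_value must be in (0, 1], got {p_value}")
    if not np.isfinite(log2fc):
        return 0.0
    if p_value >= p_threshold or abs(log2fc) < np.log2(fc_threshold):
        return 0.0
    return float(-np.log10(p_value) + abs(log2fc))


def screen_features(
    expr: ExpressionMatrix,
    sheet: Sequence[SampleAnnotation],
    config: RunConfig | None = None,
    use_q_values: bool = False,
) -> list[DiffExprRecord]:
    """Run the differential-expression screen over every testable assay.

    An assay is testable when at least ``min_detection_fraction`` of the
    samples of at least one group are detected and each group contributes
    at least one value; anything else is skipped silently.
    """
    config = config or RunConfig()
    groups = {a.sample_id: a.group for a in sheet}
    mask = np.array([groups.get(s) == "malignant" for s in expr.sample_ids])
    known = np.array([s in groups for s in expr.sample_ids])
    if not (mask & known).any() or not (~mask & known).any():
        raise ValueError("both benign and malignant samples are required")

    rows = []
    for assay in expr.assay_ids:
        col = expr.values[assay].to_numpy(dtype=float)[known]
        m = mask[known]
        det = np.isfinite(col)
        frac_mal = det[m].mean() if m.any() else 0.0
        frac_ben = det[~m].mean() if (~m).any() else 0.0
        if max(frac_mal, frac_ben) < config.min_detection_fraction:
            continue
        mal = col[m & det]
        ben = col[~m & det]
        if mal.size == 0 or ben.size == 0:
            rows.append((assay, ben.size, mal.size, np.nan, np.nan, np.nan))
            continue
        u, p = mann_whitney_u(mal, ben)
        lfc = group_fold_change(col, m)
        rows.append((assay, ben.size, mal.size, lfc, u, p))

    if not rows:
        return []
    frame = pd.DataFrame(rows, columns=["assay_id", "n_benign", "n_malignant",
                                        "log2fc", "u_stat", "p_value"])
    tested = frame["p_value"].notna()
    qv = np.full(len(frame), np.nan)
    if tested.any():
        qv[tested.to_numpy()] = multipletests(
            frame.loc[tested, "p_value"], method="fdr_bh")[1]
    frame["q_value"] = qv

    records = []
    gate_p = "q_value" if use_q_values else "p_value"
    for row in frame.itertuples(index=False):
        p_for_gate = getattr(row, gate_p)
        if np.isnan(row.p_value):
            score, direction = 0.0, "ns"
        else:
            score = combined_score(p_for_gate, row.log2fc,
                                   config.p_threshold, config.fc_threshold)
            direction = "ns" if score == 0 else ("up" if row.log2fc > 0 else "down")
        records.append(DiffExprRecord(
            row.assay_id, int(row.n_benign), int(row.n_malignant),
            float(row.log2fc), float(row.u_stat), float(row.p_value),
            float(row.q_value), score, direction))
    return records


def select_top_candidates(
    records: Sequence[DiffExprRecord], top_k: int = 3
) -> tuple[list[DiffExprRecord], list[DiffExprRecord]]:
    """Top-k up- and downregulated assays by descending combined score.

    Ties are broken by smaller p-value, then lexicographic assay id.  When a
    direction has fewer than ``top_k`` significant assays, all available are
    returned with a warning.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")

    def pick(direction: str) -> list[DiffExprRecord]:
        pool = [r for r in records if r.direction == direction]
        pool.sort(key=lambda r: (-r.combined_score, r.p_value, r.assay_id))
        if len(pool) < top_k:
            warnings.warn(
                f"only {len(pool)} {direction}-regulated candidate(s) available "
                f"(requested {top_k})", stacklevel=2)
        return pool[:top_k]

    return pick("up"), pick("down")


def records_to_frame(records: Sequence[DiffExprRecord]) -> pd.DataFrame:
    """Tabular view of screen results, one assay per row."""
    return pd.DataFrame([vars(r) for r in records])


class DifferentialScreen(BaseEstimator):
    """Scikit-learn style wrapper around the discovery screen.

    ``fit(X, y)`` expects ``X`` as a samples x assays DataFrame (or array)
    of relative expression with NaN for missing, and ``y`` as binary labels
    (1 / ``"malignant"`` = malignant).  ``transform(X)`` keeps only the
    selected candidate columns, so the screen composes with downstream
    sklearn pipelines.

    Attributes
    ----------
    results_ : DataFrame
        One row per tested assay (fold change, U, p, q, score, direction).
    up_candidates_, down_candidates_ : list of str
        Selected assay ids per direction.
    """

    def __init__(self, p_threshold: float = 0.05, fc_threshold: float = 2.0,
                 top_k: int = 3, min_detection_fraction: float = 0.5,
                 use_q_values: bool = False):
        self.p_threshold = p_threshold
        self.fc_threshold = fc_threshold
        self.top_k = top_k
        self.min_detection_fraction = min_detection_fraction
        self.use_q_values = use_q_values

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"assay_{i}" for i in range(X.shape[1])])

    def fit(self, X, y) -> "DifferentialScreen":
        frame = self._as_frame(X)
        y = np.asarray(y)
        if frame.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        is_mal = (y == "malignant") | (y == 1)
        sheet = [SampleAnnotation(str(s), "malignant" if m else "benign", "discovery")
                 for s, m in zip(frame.index.astype(str), is_mal)]
        expr = ExpressionMatrix(frame.set_axis(frame.index.astype(str)))
        config = RunConfig(p_threshold=self.p_threshold,
                           fc_threshold=self.fc_threshold, top_k=self.top_k,
                           min_detection_fraction=self.min_detection_fraction)
        records = screen_features(expr, sheet, config,
                                  use_q_values=self.use_q_values)
        up, down = select_top_candidates(records, self.top_k)
        self.results_ = records_to_frame(records)
        self.up_candidates_ = [r.assay_id for r in up]
        self.down_candidates_ = [r.assay_id for r in down]
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "results_")
        frame = self._as_frame(X)
        return frame[self.up_candidates_ + self.down_candidates_]

    def fit_transform(self, X, y) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
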