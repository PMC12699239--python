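"""End-to-end convenience wrappers tying the pipeline stages together."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .discovery import (
    DiffExprRecord,
    records_to_frame as de_frame,
    screen_features,
    select_top_candidates,
)
from .io import CtRecord, RunConfig, SampleAnnotation
from .marker_eval import MarkerPerformance, evaluate_marker
from .panel import KofNVotingClassifier
from .relquant import ExpressionMatrix, aggregate_all, build_expression_matrix

__all__ = ["quantify", "run_discovery", "run_validation"]


def quantify(
    records: Sequence[CtRecord],
    sheet: Sequence[SampleAnnotation],
    config: RunConfig,
    normalization: str = "endogenous",
) -> ExpressionMatrix:
    """Raw Ct records -> relative-expression matrix (2^-ddCt)."""
    agg = aggregate_all(records, config.negativity_threshold)
    return build_expression_matrix(agg, sheet, config, normalization=normalization)


def run_discovery(
    records: Sequence[CtRecord],
    sheet: Sequence[SampleAnnotation],
    config: RunConfig,
) -> tuple[pd.DataFrame, list[DiffExprRecord], list[DiffExprRecord]]:
    """Quantify + screen + rank; returns (DE table, up-candidates, down-candidates)."""
    expr = quantify(records, sheet, config)
    results = screen_features(expr, sheet, config)
    up, down = select_top_candidates(results, config.top_k)
    return de_frame(results), up, down


def run_validation(
    records: Sequence[CtRecord],
    sheet: Sequence[SampleAnnotation],
    config: RunConfig,
    directions: dict[str, str],
    k: int | None = None,
) -> tuple[list[MarkerPerformance], KofNVotingClassifier]:
    """Quantify + per-marker evaluation + k-of-n panel fit.

    ``directions`` maps assay_id -> 'up'/'down' (the planted or discovered
    regulation direction of each candidate).
    """
    expr = quantify(records, sheet, config)
    groups = {a.sample_id: a.group for a in sheet}
    labels = [groups[s] for s in expr.sample_ids]
    performances = [
        evaluate_marker(assay, expr.values[assay], labels, direction)
        for assay, direction in directions.items()
    ]
    clf = KofNVotingClassifier(k=k, directions=directions)
    clf.fit(expr.values[list(directions)], labels)
    return performances, clf
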