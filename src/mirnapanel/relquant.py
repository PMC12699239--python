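"""Detection calling, replicate aggregation and 2^-ddCt relative quantification.

The comparative-Ct workflow implemented here:

1. a well with Ct strictly above the negativity threshold (default 35
   cycles), or that never amplified, is **negative**;
2. technical replicates of one (sample, assay) are averaged over the
   detected wells only; a replicate SD above 0.5 cycles raises a QC flag
   but does not drop the aggregate;
3. dCt = target mean Ct minus the arithmetic mean of the reference-assay
   mean Cts of the same sample;
4. ddCt = dCt minus the mean dCt of the calibrator group (benign samples),
   and relative expression is 2^-ddCt — so by construction the geometric
   mean of relative expression over the calibrator group is 1 per assay.

Undetected values propagate as missing; they are never imputed at the
threshold, because an imputed Ct would fabricate fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CtRecord, RunConfig, SampleAnnotation, records_to_frame

__all__ = [
    "AggregatedCt",
    "ExpressionMatrix",
    "NormalizationError",
    "call_detection",
    "aggregate_replicates",
    "aggregate_all",
    "delta_ct",
    "fold_change_from_ddct",
    "build_expression_matrix",
]

REPLICATE_SD_QC_LIMIT = 0.5  # cycles


class NormalizationError(ValueError):
    """A sample cannot be normalized (no detected reference assay)."""


@dataclass(frozen=True)
class AggregatedCt:
    """Replicate-averaged Ct for one (sample, assay).

    ``mean_ct``/``sd_ct`` are computed over detected replicates only and are
    NaN when nothing was detected.  ``qc_flag`` marks replicate scatter above
    0.5 cycles.
    """

    sample_id: str
    assay_id: str
    mean_ct: float
    sd_ct: float
    n_detected: int
    detected: bool
    qc_flag: bool


def call_detection(ct: float | None, threshold: float = 35.0) -> bool:
    """True iff the well amplified at or below the negativity threshold.

    A Ct strictly over the threshold is negative; Ct equal to the threshold
    is still a detection.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return ct is not None and ct <= threshold


def aggregate_replicates(
    records: Sequence[CtRecord], threshold: float = 35.0
) -> AggregatedCt:
    """Collapse the technical replicates of one (sample, assay) well group.

    Mean and sample SD (ddof=1; 0 for a single replicate) are taken over
    detected replicates only.
    """
    if not records:
        raise ValueError("aggregate_replicates requires at least one record")
    sample_ids = {r.sample_id for r in records}
    assay_ids = {r.assay_id for r in records}
    if len(sample_ids) != 1 or len(assay_ids) != 1:
        raise ValueError("records must all belong to one (sample, assay)")
    detected = [r.ct for r in records if call_detection(r.ct, threshold)]
    n = len(detected)
    if n == 0:
        return AggregatedCt(records[0].sample_id, records[0].assay_id,
                            np.nan, np.nan, 0, False, False)
    mean = float(np.mean(detected))
    sd = float(np.std(detected, ddof=1)) if n > 1 else 0.0
    return AggregatedCt(records[0].sample_id, records[0].assay_id,
                        mean, sd, n, True, sd > REPLICATE_SD_QC_LIMIT)


def aggregate_all(
    records: Iterable[CtRecord], threshold: float = 35.0
) -> pd.DataFrame:
    """Aggregate every (sample, assay) group of a dataset at once.

    Returns a DataFrame with columns ``sample_id, assay_id, mean_ct, sd_ct,
    n_detected, detected, qc_flag`` — the tabular counterpart of
    :class:`AggregatedCt`, convenient for whole-card datasets.
    """
    df = records_to_frame(records)
    df["ok"] = df["ct"].le(threshold)  # NaN -> False
    df.loc[~df["ok"], "ct"] = np.nan
    g = df.groupby(["sample_id", "assay_id"], sort=False)["ct"]
    out = g.agg(mean_ct="mean", sd_ct="std", n_detected="count").reset_index()
    out["sd_ct"] = out["sd_ct"].where(out["n_detected"] != 1, 0.0)
    out["detected"] = out["n_detected"] > 0
    out["qc_flag"] = out["sd_ct"] > REPLICATE_SD_QC_LIMIT
    out.loc[~out["detected"], "qc_flag"] = False
    return out


def delta_ct(target: AggregatedCt, references: Sequence[AggregatedCt]) -> float:
    """dCt of one target against the reference assays of the same sample.

    Multiple references are combined by the arithmetic mean of their mean
    Cts (on the log2 expression scale this is the geometric-mean control).
    """
    if not references:
        raise NormalizationError(
            f"sample {target.sample_id!r}: no reference assay provided")
    if not target.detected:
        raise ValueError(f"target {target.assay_id!r} undetected in "
                         f"sample {target.sample_id!r}")
    undetected = [r.assay_id for r in references if not r.detected]
    if undetected:
        raise NormalizationError(
            f"sample {target.sample_id!r}: reference assay(s) "
            f"{', '.join(undetected)} undetected")
    return target.mean_ct - float(np.mean([r.mean_ct for r in references]))


def fold_change_from_ddct(ddct: float) -> float:
    """Relative expression 2^-ddCt."""
    if not np.isfinite(ddct):
        raise ValueError("ddCt must be finite")
    return float(2.0 ** (-ddct))


@dataclass
class ExpressionMatrix:
    """Samples x assays relative-expression grid (2^-ddCt), NaN = missing.

    ``values`` is indexed by sample_id with one column per target assay.
    ``calibrator_group`` records which group's mean dCt served as the ddCt
    baseline, so that provenance travels with the numbers.
    """

    values: pd.DataFrame
    reference_assays: list[str] = field(default_factory=list)
    calibrator_group: str = "benign"
    normalization: str = "endogenous"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)

    def check(self) -> None:
        """Assert internal invariants (positivity of non-missing entries)."""
        vals = self.values.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if not (vals[finite] > 0).all():
            raise ValueError("relative expression must be > 0 where present")

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, index_col="sample_id"), **kwargs)


def build_expression_matrix(
    aggregates: pd.DataFrame | Iterable[AggregatedCt],
    sheet: Sequence[SampleAnnotation],
    config: RunConfig,
    calibrator_group: str = "benign",
    normalization: str = "endogenous",
) -> ExpressionMatrix:
    """Normalize aggregated Cts into a relative-expression matrix.

    Parameters
    ----------
    aggregates
        Output of :func:`aggregate_all` (or an iterable of
        :class:`AggregatedCt`).
    sheet
        Sample annotations; only annotated samples enter the matrix.
    config
        Supplies ``reference_assay_ids`` (required for endogenous
        normalization).
    normalization
        ``"endogenous"`` (default): dCt against the declared reference
        assays.  ``"global_mean"``: dCt against the mean of all detected
        target assays of the sample — the fallback used by array platforms
        whose control behaves poorly.

    Raises
    ------
    NormalizationError
        If any sample lacks a detected reference under endogenous
        normalization.
    """
    if isinstance(aggregates, pd.DataFrame):
        agg = aggregates.copy()
    else:
        agg = pd.DataFrame([vars(a) for a in aggregates])
    if normalization not in ("endogenous", "global_mean"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    refs = list(config.reference_assay_ids)
    if normalization == "endogenous" and not refs:
        raise NormalizationError(
            "endogenous normalization requires reference_assay_ids in the config")

    groups: Mapping[str, str] = {a.sample_id: a.group for a in sheet}
    agg = agg[agg["sample_id"].isin(groups)]
    wide = agg.pivot(index="sample_id", columns="assay_id", values="mean_ct")
    wide = wide.reindex(index=[a.sample_id for a in sheet if a.sample_id in wide.index])

    target_cols = [c for c in wide.columns if c not in refs]
    if normalization == "endogenous":
        present = [r for r in refs if r in wide.columns]
        if not present:
            raise NormalizationError(
                f"reference assay(s) {', '.join(refs)} absent from the dataset")
        baseline = wide[present].mean(axis=1)
        bad = baseline.index[wide[present].isna().any(axis=1)]
        if len(bad):
            raise NormalizationError(
                f"sample(s) {', '.join(map(str, bad))}: undetected reference assay")
    else:
        baseline = wide[target_cols].mean(axis=1)

    dct = wide[target_cols].sub(baseline, axis=0)

    is_cal = dct.index.map(lambda s: groups[s] == calibrator_group).to_numpy(bool)
    if not is_cal.any():
        raise ValueError(f"no {calibrator_group!r} samples available as calibrators")
    cal_mean = dct.loc[is_cal].mean(axis=0, skipna=True)
    dead = cal_mean.index[cal_mean.isna()]
    for assay in dead:
        warnings.warn(
            f"assay {assay!r}: no detected {calibrator_group} sample; "
            "column left entirely missing", stacklevel=2)
    ddct = dct.sub(cal_mean, axis=1)
    rel = 2.0 ** (-ddct)
    rel[ddct.isna()] = np.nan

    matrix = ExpressionMatrix(rel, reference_assays=refs,
                              calibrator_group=calibrator_group,
                              normalization=normalization)
    matrix.check()
    return matrix
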