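"""Reading, writing and validation of raw qPCR Ct tables and sample sheets.

The package works from two plain-text tables, the lowest common denominator
of real-time PCR instrument exports:

* a **Ct table** with columns ``sample_id, assay_id, replicate, ct`` — one row
  per well.  Wells that never crossed the fluorescence threshold carry the
  instrument sentinel ``Undetermined`` (case-insensitive) or an empty cell.
* a **sample sheet** with columns ``sample_id, group, cohort`` assigning each
  sample a diagnostic group (``benign`` / ``malignant``) and a study phase
  (``discovery`` / ``validation``).

Both are comma-separated by default; tab-separated exports are accepted via
``dialect="tab"``.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CtRecord",
    "SampleAnnotation",
    "RunConfig",
    "ValidationIssue",
    "ValidationReport",
    "SchemaError",
    "CtParseError",
    "read_ct_table",
    "write_ct_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_dataset",
    "records_to_frame",
    "frame_to_records",
]

UNDETECTED_TOKEN = "Undetermined"

GROUP_LABELS = ("benign", "malignant")
COHORT_LABELS = ("discovery", "validation")

_CT_COLUMNS = ("sample_id", "assay_id", "replicate", "ct")
_SHEET_COLUMNS = ("sample_id", "group", "cohort")


class SchemaError(ValueError):
    """A required column is missing or a structural invariant is violated."""


class CtParseError(ValueError):
    """A Ct cell is neither numeric nor the undetected sentinel."""


@dataclass(frozen=True)
class CtRecord:
    """One raw qPCR measurement: a single well.

    ``ct`` is the cycle threshold in cycles, or ``None`` when the well never
    amplified (instrument "Undetermined").
    """

    sample_id: str
    assay_id: str
    replicate: int
    ct: float | None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if self.ct is not None:
            if not math.isfinite(self.ct) or self.ct <= 0:
                raise ValueError(f"ct must be finite and > 0, got {self.ct}")

    @property
    def detected_value(self) -> bool:
        """Whether the well amplified at all (irrespective of any threshold)."""
        return self.ct is not None


@dataclass(frozen=True)
class SampleAnnotation:
    """Group and cohort membership of one sample."""

    sample_id: str
    group: str
    cohort: str

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"group must be one of {GROUP_LABELS}, got {self.group!r}"
            )
        if self.cohort not in COHORT_LABELS:
            raise ValueError(
                f"cohort must be one of {COHORT_LABELS}, got {self.cohort!r}"
            )


@dataclass
class RunConfig:
    """Analysis-wide settings shared by the pipeline stages.

    Parameters
    ----------
    negativity_threshold : float
        Ct above which a well is called negative (undetected), in cycles.
    reference_assay_ids : list of str
        Endogenous-control assays used for within-sample normalization.
    min_detection_fraction : float
        Minimum fraction of detected samples (in at least one group) for an
        assay to be testable in the screen.
    p_threshold, fc_threshold : float
        Significance and linear fold-change gates of the combined score.
    top_k : int
        Number of candidates to carry per direction into validation.
    rng_seed : int
        Seed for any stochastic step.
    """

    negativity_threshold: float = 35.0
    reference_assay_ids: list[str] = field(default_factory=list)
    min_detection_fraction: float = 0.5
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    top_k: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.negativity_threshold <= 0:
            raise ValueError("negativity_threshold must be > 0")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 <= self.min_detection_fraction <= 1:
            raise ValueError("min_detection_fraction must be in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a plain ``key = value`` text file (# comments allowed)."""
        kwargs: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise SchemaError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise SchemaError(f"{path}:{lineno}: unknown config key {key!r}")
            if key == "reference_assay_ids":
                kwargs[key] = [a.strip() for a in value.split(",") if a.strip()]
            elif key in ("top_k", "rng_seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


def _delimiter(dialect: str) -> str:
    if dialect in ("comma", "csv", ","):
        return ","
    if dialect in ("tab", "tsv", "\t"):
        return "\t"
    raise ValueError(f"unknown dialect {dialect!r}; use 'comma' or 'tab'")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_ct_cell(value, row_number: int, path) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text == "" or text.lower() == UNDETECTED_TOKEN.lower():
        return None
    try:
        return float(text)
    except ValueError:
        raise CtParseError(
            f"{path}: row {row_number}: Ct value {text!r} is neither numeric "
            f"nor {UNDETECTED_TOKEN!r}"
        ) from None


def read_ct_table(path: str | Path, dialect: str = "comma") -> list[CtRecord]:
    """Read a long-format Ct table into :class:`CtRecord` objects.

    Raises
    ------
    SchemaError
        If a required column is missing or a (sample, assay, replicate)
        triple occurs more than once.
    CtParseError
        If a Ct cell is neither numeric nor the ``Undetermined`` sentinel.
    """
    df = pd.read_csv(path, sep=_delimiter(dialect), dtype=str, keep_default_na=False)
    _require_columns(df, _CT_COLUMNS, path)
    records: list[CtRecord] = []
    seen: set[tuple[str, str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header row
        try:
            replicate = int(row.replicate)
        except ValueError:
            raise CtParseError(
                f"{path}: row {i}: replicate {row.replicate!r} is not an integer"
            ) from None
        key = (row.sample_id, row.assay_id, replicate)
        if key in seen:
            raise SchemaError(
                f"{path}: duplicate measurement for sample={key[0]!r} "
                f"assay={key[1]!r} replicate={key[2]}"
            )
        seen.add(key)
        records.append(
            CtRecord(row.sample_id, row.assay_id, replicate, _parse_ct_cell(row.ct, i, path))
        )
    return records


def write_ct_table(
    records: Iterable[CtRecord], path: str | Path, dialect: str = "comma"
) -> None:
    """Write records back to disk; undetected wells become ``Undetermined``."""
    df = records_to_frame(records)
    df["ct"] = df["ct"].map(lambda v: UNDETECTED_TOKEN if pd.isna(v) else repr(float(v)))
    df.to_csv(path, sep=_delimiter(dialect), index=False)


def read_sample_sheet(path: str | Path, dialect: str = "comma") -> list[SampleAnnotation]:
    """Read the sample sheet; unknown group or cohort labels are rejected."""
    df = pd.read_csv(path, sep=_delimiter(dialect), dtype=str, keep_default_na=False)
    _require_columns(df, _SHEET_COLUMNS, path)
    annotations = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.sample_id in seen:
            raise SchemaError(f"{path}: duplicate sample_id {row.sample_id!r}")
        seen.add(row.sample_id)
        annotations.append(SampleAnnotation(row.sample_id, row.group, row.cohort))
    return annotations


def write_sample_sheet(
    annotations: Iterable[SampleAnnotation], path: str | Path, dialect: str = "comma"
) -> None:
    pd.DataFrame([dataclasses.asdict(a) for a in annotations]).to_csv(
        path, sep=_delimiter(dialect), index=False
    )


def records_to_frame(records: Iterable[CtRecord]) -> pd.DataFrame:
    """Long DataFrame view of Ct records (undetected encoded as NaN)."""
    return pd.DataFrame(
        [(r.sample_id, r.assay_id, r.replicate, math.nan if r.ct is None else r.ct)
         for r in records],
        columns=list(_CT_COLUMNS),
    )


def frame_to_records(df: pd.DataFrame) -> list[CtRecord]:
    return [
        CtRecord(str(r.sample_id), str(r.assay_id), int(r.replicate),
                 None if pd.isna(r.ct) else float(r.ct))
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    message: str
    blocking: bool = True


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(issue.blocking for issue in self.issues)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if not self.issues:
            return "dataset OK: no issues"
        return "\n".join(
            f"[{'BLOCK' if i.blocking else 'warn '}] {i.code}: {i.message}"
            for i in self.issues
        )


def validate_dataset(
    records: Sequence[CtRecord],
    sheet: Sequence[SampleAnnotation],
    reference_assay_ids: Sequence[str] = (),
) -> ValidationReport:
    """Cross-check a Ct table against its sample sheet.

    The report lists, without mutating anything:

    * samples measured but absent from the sheet (blocking),
    * annotated samples with no measurements (warning),
    * samples lacking any measurement of a reference assay (blocking when
      references are declared),
    * uneven replicate counts across (sample, assay) pairs (warning).
    """
    report = ValidationReport()
    sheet_ids = {a.sample_id for a in sheet}
    measured_ids = {r.sample_id for r in records}

    for sid in sorted(measured_ids - sheet_ids):
        report.issues.append(ValidationIssue(
            "orphan-sample", f"sample {sid!r} has Ct data but no annotation"))
    for sid in sorted(sheet_ids - measured_ids):
        report.issues.append(ValidationIssue(
            "unmeasured-sample", f"sample {sid!r} annotated but has no Ct data",
            blocking=False))

    if reference_assay_ids:
        refs = set(reference_assay_ids)
        with_ref = {r.sample_id for r in records if r.assay_id in refs}
        for sid in sorted(measured_ids - with_ref):
            report.issues.append(ValidationIssue(
                "missing-reference",
                f"sample {sid!r} has no measurement of any reference assay "
                f"({', '.join(sorted(refs))})"))

    counts = Counter((r.sample_id, r.assay_id) for r in records)
    if counts:
        modal = Counter(counts.values()).most_common(1)[0][0]
        uneven = [k for k, n in counts.items() if n != modal]
        if uneven:
            sid, aid = min(uneven)
            report.issues.append(ValidationIssue(
                "uneven-replicates",
                f"{len(uneven)} (sample, assay) pair(s) deviate from the modal "
                f"replicate count {modal} (e.g. {sid!r}/{aid!r})",
                blocking=False))
    return report
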