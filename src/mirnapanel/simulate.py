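"""Synthetic raw-Ct cohorts with planted group effects.

The generator emulates the statistical structure the downstream analysis
assumes, on the raw Ct scale:

* each sample carries a latent reference Ct drawn around the reference
  assay's mean (sample-to-sample input variation);
* each (sample, assay) has a latent dCt drawn from
  Normal(baseline - group * planted_log2fc, baseline_sd) — malignant
  samples of an upregulated assay amplify earlier by exactly the planted
  log2 fold change, because one PCR cycle is one doubling;
* every replicate adds independent technical noise;
* wells whose Ct lands above the negativity threshold are emitted as
  undetected when dropout is enabled, mirroring the Ct > 35 rule.

Defaults follow qPCR convention: biological spread 1.5 cycles per assay,
technical replicate scatter 0.15 cycles.  ``preset_paper_shape`` mirrors a
two-phase biomarker study: a 768-assay discovery card on 5 benign + 6
malignant samples with 50 planted effects (27 up, 23 down), and a 6-assay
+ 1 reference validation panel on 18 benign + 17 malignant samples run in
triplicate with planted log2 fold changes of +/-2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CtRecord, SampleAnnotation

__all__ = [
    "AssaySpec",
    "SyntheticCohortSpec",
    "TwoPhaseStudySpec",
    "simulate_cohort",
    "preset_paper_shape",
    "VALIDATION_MARKERS",
]

DEFAULT_BASELINE_SD = 1.5   # cycles; biological sample-to-sample spread
DEFAULT_REPLICATE_SD = 0.15  # cycles; technical well-to-well scatter

# The six validation candidates with their planted regulation directions.
VALIDATION_MARKERS = (
    ("miR-181c-5p", "up"),
    ("miR-182b-5p", "up"),
    ("miR-196b-5p", "up"),
    ("miR-145-5p", "down"),
    ("miR-199a-3p", "down"),
    ("miR-214-3p", "down"),
)
REFERENCE_ASSAY = "RNU48"


@dataclass(frozen=True)
class AssaySpec:
    """Latent parameters of one target assay.

    ``baseline_mean_ct`` is the mean dCt (cycles above the reference) of
    benign samples; ``planted_log2fc`` shifts malignant samples by
    -planted_log2fc cycles (up = earlier amplification).
    """

    assay_id: str
    baseline_mean_ct: float
    baseline_sd_ct: float = DEFAULT_BASELINE_SD
    planted_log2fc: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_sd_ct < 0:
            raise ValueError("baseline_sd_ct must be >= 0")


@dataclass(frozen=True)
class ReferenceSpec:
    assay_id: str
    mean_ct: float = 20.0
    sd_ct: float = 0.5

    def __post_init__(self) -> None:
        if self.sd_ct < 0:
            raise ValueError("sd_ct must be >= 0")


@dataclass
class SyntheticCohortSpec:
    """Everything needed to draw one cohort reproducibly."""

    n_benign: int
    n_malignant: int
    assays: list[AssaySpec]
    reference_assays: list[ReferenceSpec]
    cohort: str = "validation"
    n_replicates: int = 3
    replicate_sd: float = DEFAULT_REPLICATE_SD
    negativity_threshold: float = 35.0
    dropout_above_threshold: bool = True
    rng_seed: int = 0
    sample_prefix: str = "S"

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("both groups need at least one sample")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if not self.assays:
            raise ValueError("at least one target assay is required")
        if not self.reference_assays:
            raise ValueError("at least one reference assay is required")


@dataclass
class TwoPhaseStudySpec:
    """Discovery card + validation panel, as in a two-phase biomarker study."""

    discovery: SyntheticCohortSpec
    validation: SyntheticCohortSpec


def simulate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[CtRecord], list[SampleAnnotation], pd.DataFrame]:
    """Draw one cohort: Ct records, sample sheet, and the planted truth.

    The truth table has one row per target assay with its planted log2 fold
    change and direction (``up``/``down``/``none``).  The same seed always
    reproduces the identical dataset.
    """
    rng = np.random.default_rng(spec.rng_seed)
    groups = ["benign"] * spec.n_benign + ["malignant"] * spec.n_malignant
    n = len(groups)
    width = len(str(n))
    sample_ids = [f"{spec.sample_prefix}{i + 1:0{width}d}" for i in range(n)]
    sheet = [SampleAnnotation(s, g, spec.cohort) for s, g in zip(sample_ids, groups)]
    is_mal = np.array([g == "malignant" for g in groups])

    records: list[CtRecord] = []

    def emit(sample: str, assay: str, true_ct: float) -> None:
        cts = true_ct + rng.normal(0.0, spec.replicate_sd, spec.n_replicates)
        for rep, ct in enumerate(cts, start=1):
            undetected = spec.dropout_above_threshold and ct > spec.negativity_threshold
            records.append(CtRecord(sample, assay, rep,
                                    None if undetected else float(max(ct, 1e-6))))

    # Latent per-sample reference level: true input-amount variation.
    ref_levels = {}
    for ref in spec.reference_assays:
        ref_levels[ref.assay_id] = ref.mean_ct + rng.normal(0.0, ref.sd_ct, n)
    sample_ref = np.mean(np.column_stack(list(ref_levels.values())), axis=1)

    for ref in spec.reference_assays:
        for i, sample in enumerate(sample_ids):
            emit(sample, ref.assay_id, float(ref_levels[ref.assay_id][i]))

    truth_rows = []
    for assay in spec.assays:
        shift = np.where(is_mal, -assay.planted_log2fc, 0.0)
        dcts = rng.normal(assay.baseline_mean_ct + shift, assay.baseline_sd_ct)
        for i, sample in enumerate(sample_ids):
            emit(sample, assay.assay_id, float(sample_ref[i] + dcts[i]))
        direction = ("none" if assay.planted_log2fc == 0
                     else "up" if assay.planted_log2fc > 0 else "down")
        truth_rows.append((assay.assay_id, assay.baseline_mean_ct,
                           assay.planted_log2fc, direction))
    truth = pd.DataFrame(truth_rows, columns=["assay_id", "baseline_mean_ct",
                                              "planted_log2fc", "direction"])
    return records, sheet, truth


def _discovery_assays(n_assays: int = 768, n_up: int = 27, n_down: int = 23,
                      effect_range: tuple[float, float] = (1.2, 4.0),
                      baseline_range: tuple[float, float] = (3.0, 13.0)) -> list[AssaySpec]:
    """Deterministic discovery-card layout with planted effects.

    Effect magnitudes are evenly spaced across ``effect_range`` per
    direction (so a clear top-3 exists); baselines cycle across
    ``baseline_range`` so a realistic minority of assays sits close to the
    detection limit.
    """
    up = np.linspace(effect_range[1], effect_range[0], n_up)
    down = -np.linspace(effect_range[1], effect_range[0], n_down)
    effects = np.zeros(n_assays)
    effects[:n_up] = up
    effects[n_up:n_up + n_down] = down
    baselines = baseline_range[0] + (np.arange(n_assays) * 37 % n_assays) \
        / max(n_assays - 1, 1) * (baseline_range[1] - baseline_range[0])
    return [AssaySpec(f"miR-A{i + 1:03d}", float(baselines[i]),
                      planted_log2fc=float(effects[i]))
            for i in range(n_assays)]


def preset_paper_shape(rng_seed: int = 0, n_assays: int = 768) -> TwoPhaseStudySpec:
    """Two-cohort study preset mirroring the published design.

    Discovery: 5 benign + 6 malignant samples on a card of ``n_assays``
    single-well assays (plus the reference), 27 planted up and 23 planted
    down.  Validation: 18 benign + 17 malignant samples on the six named
    candidate markers (planted log2FC +/-2) plus the reference, in
    triplicate.
    """
    discovery = SyntheticCohortSpec(
        n_benign=5, n_malignant=6,
        assays=_discovery_assays(n_assays=n_assays),
        reference_assays=[ReferenceSpec(REFERENCE_ASSAY)],
        cohort="discovery", n_replicates=1,
        rng_seed=rng_seed, sample_prefix="D",
    )
    validation = SyntheticCohortSpec(
        n_benign=18, n_malignant=17,
        assays=[AssaySpec(name, baseline_mean_ct=6.0,
                          planted_log2fc=2.0 if direction == "up" else -2.0)
                for name, direction in VALIDATION_MARKERS],
        reference_assays=[ReferenceSpec(REFERENCE_ASSAY)],
        cohort="validation", n_replicates=3,
        rng_seed=rng_seed + 1, sample_prefix="V",
    )
    return TwoPhaseStudySpec(discovery, validation)


def null_cohort_spec(n_assays: int = 400, n_benign: int = 18, n_malignant: int = 17,
                     rng_seed: int = 0) -> SyntheticCohortSpec:
    """A cohort with no planted effect anywhere — for type-I error studies."""
    assays = [AssaySpec(f"null-{i + 1:04d}", baseline_mean_ct=6.0)
              for i in range(n_assays)]
    return SyntheticCohortSpec(
        n_benign=n_benign, n_malignant=n_malignant, assays=assays,
        reference_assays=[ReferenceSpec(REFERENCE_ASSAY)],
        cohort="validation", n_replicates=3, rng_seed=rng_seed,
        dropout_above_threshold=False,
    )
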