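import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirnapanel.io import CtRecord, RunConfig, SampleAnnotation
from mirnapanel.relquant import (
    AggregatedCt,
    NormalizationError,
    aggregate_all,
    aggregate_replicates,
    build_expression_matrix,
    call_detection,
    delta_ct,
    fold_change_from_ddct,
)


def recs(sample, assay, cts):
    return [CtRecord(sample, assay, i + 1, ct) for i, ct in enumerate(cts)]


class TestCallDetection:
    @pytest.mark.parametrize("ct,expected", [
        (36.0, False),   # strictly over the threshold is negative
        (35.0, True),    # the boundary itself is still a detection
        (None, False),   # never amplified
        (10.0, True),
    ])
    def test_threshold_rule(self, ct, expected):
        assert call_detection(ct, 35.0) is expected

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            call_detection(20.0, 0.0)


class TestAggregateReplicates:
    def test_identical_triplicate(self):
        agg = aggregate_replicates(recs("S1", "m1", [25.0, 25.0, 25.0]))
        assert agg.mean_ct == 25.0 and agg.sd_ct == 0.0
        assert agg.detected and agg.n_detected == 3 and not agg.qc_flag

    def test_scattered_triplicate(self):
        agg = aggregate_replicates(recs("S1", "m1", [24.8, 25.0, 25.2]))
        assert agg.mean_ct == pytest.approx(25.0)
        assert agg.sd_ct == pytest.approx(0.2)
        assert not agg.qc_flag

    def test_all_undetected(self):
        agg = aggregate_replicates(recs("S1", "m1", [None, None]))
        assert not agg.detected and agg.n_detected == 0
        assert np.isnan(agg.mean_ct)

    def test_mean_over_detected_replicates_only(self):
        agg = aggregate_replicates(recs("S1", "m1", [25.0, None, 27.0]))
        assert agg.n_detected == 2 and agg.mean_ct == pytest.approx(26.0)

    def test_wide_scatter_sets_qc_flag(self):
        agg = aggregate_replicates(recs("S1", "m1", [24.0, 26.0]))
        assert agg.qc_flag  # sd ~1.41 > 0.5 cycles

    def test_rejects_mixed_wells(self):
        with pytest.raises(ValueError):
            aggregate_replicates([CtRecord("S1", "m1", 1, 25.0),
                                  CtRecord("S2", "m1", 1, 25.0)])

    def test_aggregate_all_matches_single_aggregation(self):
        records = recs("S1", "m1", [24.8, 25.0, 25.2]) + recs("S1", "m2", [None, 30.0])
        table = aggregate_all(records).set_index("assay_id")
        assert table.loc["m1", "mean_ct"] == pytest.approx(25.0)
        assert table.loc["m1", "sd_ct"] == pytest.approx(0.2)
        assert table.loc["m2", "n_detected"] == 1 and table.loc["m2", "sd_ct"] == 0.0


def agg(sample, assay, mean, detected=True):
    return AggregatedCt(sample, assay, mean if detected else np.nan,
                        0.0, 3 if detected else 0, detected, False)


class TestDeltaCt:
    def test_single_reference(self):
        assert delta_ct(agg("S1", "t", 25.0), [agg("S1", "r", 20.0)]) == 5.0

    def test_multiple_references_averaged(self):
        refs = [agg("S1", "r1", 20.0), agg("S1", "r2", 22.0)]
        assert delta_ct(agg("S1", "t", 25.0), refs) == pytest.approx(4.0)

    def test_undetected_reference_raises(self):
        with pytest.raises(NormalizationError):
            delta_ct(agg("S1", "t", 25.0), [agg("S1", "r", 0, detected=False)])


@pytest.mark.parametrize("ddct,expected", [(0.0, 1.0), (-2.0, 4.0), (1.0, 0.5)])
def test_fold_change_closed_form(ddct, expected):
    assert fold_change_from_ddct(ddct) == expected


def test_fold_change_rejects_nonfinite():
    with pytest.raises(ValueError):
        fold_change_from_ddct(float("nan"))


class TestBuildExpressionMatrix:
    def test_planted_two_cycle_shift_gives_fourfold(self, toy_records, toy_sheet,
                                                    toy_config):
        expr = build_expression_matrix(aggregate_all(toy_records), toy_sheet, toy_config)
        col = expr.values["miR-X"]
        assert col["M1"] == pytest.approx(4.0)
        assert col["B1"] == pytest.approx(1.0)  # benign sample at the benign mean

    def test_calibrator_geometric_mean_is_one(self, toy_records, toy_sheet, toy_config):
        expr = build_expression_matrix(aggregate_all(toy_records), toy_sheet, toy_config)
        benign = expr.values.loc[["B1", "B2"], "miR-X"]
        assert np.exp(np.log(benign).mean()) == pytest.approx(1.0)

    def test_undetected_entries_are_missing(self, toy_records, toy_sheet, toy_config):
        records = toy_records + [CtRecord("B1", "miR-Y", 1, 27.0),
                                 CtRecord("B2", "miR-Y", 1, 27.0),
                                 CtRecord("M1", "miR-Y", 1, None),
                                 CtRecord("M2", "miR-Y", 1, 25.0)]
        expr = build_expression_matrix(aggregate_all(records), toy_sheet, toy_config)
        assert np.isnan(expr.values.loc["M1", "miR-Y"])
        assert np.isfinite(expr.values.loc["M2", "miR-Y"])

    def test_assay_without_calibrator_data_left_missing_with_warning(
            self, toy_records, toy_sheet, toy_config):
        records = toy_records + [CtRecord("B1", "miR-Z", 1, None),
                                 CtRecord("B2", "miR-Z", 1, None),
                                 CtRecord("M1", "miR-Z", 1, 25.0)]
        with pytest.warns(UserWarning, match="miR-Z"):
            expr = build_expression_matrix(aggregate_all(records), toy_sheet, toy_config)
        assert expr.values["miR-Z"].isna().all()

    def test_undetected_reference_is_an_error(self, toy_records, toy_sheet, toy_config):
        records = [r for r in toy_records
                   if not (r.sample_id == "B1" and r.assay_id == "REF")]
        records.append(CtRecord("B1", "REF", 1, None))
        with pytest.raises(NormalizationError, match="B1"):
            build_expression_matrix(aggregate_all(records), toy_sheet, toy_config)

    def test_global_mean_normalization_runs_without_reference(self, toy_records,
                                                              toy_sheet):
        config = RunConfig()  # no reference declared
        targets = [r for r in toy_records if r.assay_id != "REF"]
        extra = [CtRecord(s, "miR-W", 1, 26.0) for s in ("B1", "B2", "M1", "M2")]
        expr = build_expression_matrix(aggregate_all(targets + extra), toy_sheet,
                                       config, normalization="global_mean")
        assert expr.normalization == "global_mean"
        assert expr.values.notna().all().all()


@settings(deadline=None, derandomize=True)
@given(shift=st.floats(-5, 5), target=st.floats(22, 30), ref=st.floats(15, 21))
def test_delta_ct_invariant_under_per_sample_shift(shift, target, ref):
    """Adding a constant to every Ct of a sample leaves its dCt unchanged."""
    base = delta_ct(agg("S1", "t", target), [agg("S1", "r", ref)])
    shifted = delta_ct(agg("S1", "t", target + shift), [agg("S1", "r", ref + shift)])
    assert shifted == pytest.approx(base)


def test_lower_target_ct_means_higher_expression(toy_sheet, toy_config):
    """Earlier amplification (lower Ct) maps to strictly higher 2^-ddCt."""
    def matrix_with(m1_ct):
        rows = [CtRecord(s, "REF", 1, 20.0) for s in ("B1", "B2", "M1", "M2")]
        rows += [CtRecord("B1", "miR-X", 1, 27.0), CtRecord("B2", "miR-X", 1, 27.0),
                 CtRecord("M1", "miR-X", 1, m1_ct), CtRecord("M2", "miR-X", 1, 25.0)]
        return build_expression_matrix(aggregate_all(rows), toy_sheet, toy_config)

    low = matrix_with(24.0).values.loc["M1", "miR-X"]
    high = matrix_with(26.0).values.loc["M1", "miR-X"]
    assert low > high
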