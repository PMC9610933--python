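"""Tests for the recovery/depth accuracy bookkeeping."""

import pytest

from sedsim import (
    StudyRecord,
    assess_regimen,
    observed_recovery_time,
    pooled_accuracy_margin,
    round_half_up,
    validate_all,
)


def _record(rid="x", target="moderate", T_p=10.0, T_rs=5.0, sd=2.0):
    return StudyRecord(
        regimen_id=rid, source="s", sedation_target=target,
        recovery_scale="MOAA/S", T_p=T_p, T_rs=T_rs, T_rs_sd=sd,
    )


class TestObservedRecoveryTime:
    def test_symmetric_range(self):
        rec = _record(T_p=25.0, T_rs=9.4, sd=12.8)
        T_ro, rng = observed_recovery_time(rec, induction=3.0)
        assert T_ro == pytest.approx(37.4)
        assert rng == (pytest.approx(24.6), pytest.approx(50.2))

    def test_one_sided_range_from_negative_sd(self):
        rec = _record(T_p=8.0, T_rs=30.0, sd=-20.0)
        T_ro, rng = observed_recovery_time(rec, induction=3.0)
        assert T_ro == pytest.approx(41.0)
        assert rng == (pytest.approx(21.0), pytest.approx(41.0))

    def test_degenerate_zero_inputs(self):
        rec = _record(T_p=1e-9, T_rs=0.0, sd=0.0)
        T_ro, rng = observed_recovery_time(rec, induction=3.0)
        assert T_ro == pytest.approx(3.0)
        assert rng[0] == pytest.approx(rng[1])


class TestPooledMargin:
    def test_single_record(self):
        mean, half = pooled_accuracy_margin([_record(T_rs=10.0)])
        assert (mean, half) == (10.0, 5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pooled_accuracy_margin([])

    def test_fixture_mean_and_margin(self, fx):
        mean, half = pooled_accuracy_margin(fx.study_records)
        assert round_half_up(mean) == 14.9
        assert round_half_up(half) == 7.4


class TestAssessRegimen:
    def test_early_prediction_flagged_out_of_range(self):
        rec = _record(rid="3", T_p=11.0, T_rs=11.0, sd=3.0)
        res = assess_regimen(rec, T_rm=16.4, deep_ratio=0.0, half_margin=7.4)
        assert not res.within_range
        assert res.abs_error == pytest.approx(-8.6)
        assert not res.within_margin

    def test_deep_prediction_agrees_with_deep_target(self):
        rec = _record(rid="6", target="deep", T_p=22.0, T_rs=30.0, sd=-20.0)
        res = assess_regimen(rec, T_rm=48.1, deep_ratio=1.0, half_margin=7.4)
        assert res.predicted_depth == "deep"
        assert res.depth_agrees is True

    def test_exact_prediction_has_zero_error(self):
        rec = _record(T_p=10.0, T_rs=5.0, sd=2.0)
        res = assess_regimen(rec, T_rm=18.0, deep_ratio=None, half_margin=7.4)
        assert res.abs_error == 0.0
        assert res.pct_error == 0.0
        assert res.within_margin

    def test_depth_tie_classifies_moderate(self):
        res = assess_regimen(_record(target="deep"), 10.0, deep_ratio=0.5, half_margin=7.4)
        assert res.predicted_depth == "moderate"
        assert res.depth_agrees is False

    def test_unreported_target_not_evaluable(self):
        res = assess_regimen(_record(target="not_reported"), 10.0, 0.9, 7.4)
        assert res.depth_agrees is None


class TestValidateAll:
    def test_duplicate_ids_rejected(self):
        recs = [_record(rid="1"), _record(rid="1")]
        with pytest.raises(ValueError, match="duplicate"):
            validate_all(recs, {"1": (10.0, None)})

    def test_missing_prediction_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            validate_all([_record(rid="1")], {})

    def test_reference_mode_summary_counts(self, fx):
        """Reference predictions reproduce the published accuracy bookkeeping."""
        preds = {o.regimen_id: (o.T_rm, o.deep_ratio) for o in fx.reference_outcomes}
        report = validate_all(fx.study_records, preds)
        assert report.n_recovery_accurate_range == 8
        assert report.n_recovery_accurate_margin == 8
        within = {r.regimen_id: r.within_margin for r in report.results}
        assert within == {rid: rid != "3" for rid in within}
        assert report.n_depth_agree == 5
        assert report.n_depth_evaluable == 7
        assert round_half_up(report.overall_accuracy, 0) == 81

    def test_reference_mode_post_procedure_lag(self, fx):
        """Mean lag after procedure end for the slow-recovery regimens is 21.62 min."""
        preds = {o.regimen_id: (o.T_rm, o.deep_ratio) for o in fx.reference_outcomes}
        report = validate_all(fx.study_records, preds)
        lags = {
            r.regimen_id: r.T_rm - 3.0 - fx.record(r.regimen_id).T_p for r in report.results
        }
        slow = ["1", "4", "5", "6", "9"]
        assert sum(lags[i] for i in slow) / len(slow) == pytest.approx(21.62)

    def test_reference_mode_percent_error_bound(self, fx):
        """Accurate regimens deviate at most 18% from the observed recovery time."""
        preds = {o.regimen_id: (o.T_rm, o.deep_ratio) for o in fx.reference_outcomes}
        report = validate_all(fx.study_records, preds)
        accurate = [r for r in report.results if r.within_range]
        assert max(abs(r.pct_error) for r in accurate) <= 0.18


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(-0.25, 1) == -0.3
    assert round_half_up(81.25, 0) == 81.0
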