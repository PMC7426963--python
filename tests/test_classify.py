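"""B1/B2/B3 decision rule, the RMSD table and cross-couple trends."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fabcompare import (
    ClassThresholds,
    CoupleReport,
    LoopSignal,
    classify_couple,
    rmsd_table,
    trend_summary,
)
from fabcompare.geometry import AngleChange, AngleMetrics
from fabcompare.superpose import matched_backbone

from oracles import brute_force_rmsd


def _signal(peak, ratio):
    return LoopSignal(peak=peak, peak_index=135, baseline=peak / ratio
                      if ratio else 0.0, ratio=ratio)


class TestDecisionRule:
    @pytest.mark.parametrize(
        "avg, peak, ratio, expected",
        [
            (37.0, 2.0, 6.0, "B1"),      # large reorientation dominates
            (2.0, 2.5, 6.0, "B2"),       # shape kept, loop signal present
            (3.0, 0.3, 1.1, "B3"),       # CDR-local change only
            (16.0, 0.0, 1.0, "B1"),      # smallest observed B1 angle
            (4.0, 2.0, 1.5, "B3"),       # ratio below threshold blocks B2
            (4.0, 1.0, 6.0, "B3"),       # peak below threshold blocks B2
        ],
    )
    def test_reference_cases(self, avg, peak, ratio, expected):
        assert classify_couple(avg, _signal(peak, ratio)) == expected

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        avg=st.floats(0, 60, allow_nan=False),
        bump=st.floats(0, 30),
        peak=st.floats(0, 5),
        ratio=st.floats(0, 20),
    )
    def test_monotone_in_angle_and_loop(self, avg, bump, peak, ratio):
        """Raising the angle never demotes B1; raising the loop never
        demotes B2 to B3."""
        order = {"B3": 0, "B2": 1, "B1": 2}
        base = classify_couple(avg, _signal(peak, ratio))
        more_angle = classify_couple(avg + bump, _signal(peak, ratio))
        assert order[more_angle] >= order[base]
        more_loop = classify_couple(avg, _signal(peak + 1.0, ratio + 1.0))
        if base == "B2":
            assert more_loop in ("B1", "B2")

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            ClassThresholds(tau_angle=-1.0)

    def test_nonfinite_angle_rejected(self):
        with pytest.raises(ValueError):
            classify_couple(float("nan"), _signal(1, 1))


class TestRmsdTable:
    def test_identical_fabs_all_zero(self, identical_couple):
        table, _ = rmsd_table(
            identical_couple.free_heavy, identical_couple.free_light,
            identical_couple.bound_heavy, identical_couple.bound_light,
        )
        assert (table.to_numpy() < 1e-9).all()

    def test_hinge_couple_constant_exceeds_variable(self, couple_b1):
        table, _ = rmsd_table(
            couple_b1.free_heavy, couple_b1.free_light,
            couple_b1.bound_heavy, couple_b1.bound_light,
        )
        assert table.loc["constant", "heavy"] > table.loc["variable", "heavy"]
        assert table.loc["constant", "light"] > table.loc["variable", "light"]

    def test_cells_match_brute_force_under_single_transform(self, couple_b3):
        free_h, free_l = couple_b3.free_heavy, couple_b3.free_light
        bound_h, bound_l = couple_b3.bound_heavy, couple_b3.bound_light
        table, transform = rmsd_table(free_h, free_l, bound_h, bound_l)
        for chain_label, f, b in (("heavy", free_h, bound_h),
                                  ("light", free_l, bound_l)):
            for region, span in (("variable", (1, 105)),
                                 ("linker", (106, 113)),
                                 ("constant", (114, 218))):
                cb, cf, _, _ = matched_backbone(b, f, list(range(span[0],
                                                                 span[1] + 1)))
                expected = brute_force_rmsd(transform.transform(cb), cf)
                assert table.loc[region, chain_label] == pytest.approx(
                    expected, abs=1e-12)


def _fake_report(couple_id, entire_h, entire_l, vl, cl, vh, ch):
    table = pd.DataFrame({
        "heavy": {"entire": entire_h, "variable": vh, "linker": 0.2,
                  "constant": ch},
        "light": {"entire": entire_l, "variable": vl, "linker": 0.2,
                  "constant": cl},
    })
    metrics = AngleMetrics(120.0, 110.0, 40.0, 40.0, 10.0,
                           (85, 108, 147), (85, 108, 147))
    return CoupleReport(
        couple_id=couple_id,
        angle_metrics_free=metrics, angle_metrics_bound=metrics,
        angle_change=AngleChange(0.0, 0.0, 0.0),
        rmsd_table=table,
        c_loop1_signal_heavy=_signal(0.1, 1.0),
        c_loop1_signal_light=None,
        class_label="B3",
        thresholds_used=ClassThresholds(),
    )


class TestTrendSummary:
    def test_single_couple_buckets(self):
        rep = _fake_report("a/b", entire_h=2.0, entire_l=1.0,
                           vl=0.5, cl=1.5, vh=0.6, ch=2.5)
        trends = trend_summary([rep])
        assert trends["counts"]["light_lt_heavy"] == 1
        assert trends["counts"]["cl_gt_vl"] == 1
        assert trends["counts"]["ch_gt_vh"] == 1

    def test_equal_values_fall_in_none_bucket(self):
        rep = _fake_report("a/b", entire_h=1.0, entire_l=1.0,
                           vl=0.5, cl=0.5, vh=0.6, ch=0.6)
        trends = trend_summary([rep])
        assert trends["counts"]["light_eq_heavy"] == 1
        assert trends["counts"]["cl_eq_vl"] == 1
        assert trends["counts"]["ch_eq_vh"] == 1

    def test_eight_couple_tally_pattern(self):
        """Eight couples built to show: light < heavy in all 8; CL < VL in
        3; CL > VL in 5; CH < VH in 1; CH > VH in 7."""
        reports = []
        for i in range(8):
            cl, vl = (0.4, 0.9) if i < 3 else (0.9, 0.4)
            ch, vh = (0.5, 1.0) if i < 1 else (1.2, 0.5)
            reports.append(_fake_report(f"c{i}", entire_h=2.0, entire_l=1.0,
                                        vl=vl, cl=cl, vh=vh, ch=ch))
        counts = trend_summary(reports)["counts"]
        assert counts["light_lt_heavy"] == 8
        assert counts["cl_lt_vl"] == 3
        assert counts["cl_gt_vl"] == 5
        assert counts["ch_lt_vh"] == 1
        assert counts["ch_gt_vh"] == 7

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            trend_summary([])


class TestReportAudit:
    def test_class_rederivable_from_stored_fields(self, couple_b1):
        from fabcompare import analyze_prepared_couple
        rep = analyze_prepared_couple(
            "b1", couple_b1.free_heavy, couple_b1.free_light,
            couple_b1.bound_heavy, couple_b1.bound_light)
        assert rep.rederive_class() == rep.class_label == "B1"
        # and from the serialized form alone
        data = json.loads(rep.to_json())
        saved = classify_couple(
            data["angle_change"]["average_abs_change_deg"],
            LoopSignal(**data["c_loop1_signal_heavy"]),
            ClassThresholds(**data["thresholds_used"]),
        )
        assert saved == rep.class_label
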