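"""Tiered calibration tolerances, CRC limits, validity windows and triggers."""

from __future__ import annotations

from datetime import date, datetime, timezone

import numpy as np
import pandas as pd
import pytest

import petvalid as pv
from petvalid.criteria import (
    CrcCriteria,
    Finding,
    ValidationDecision,
    decision_to_json,
    decision_to_markdown,
)
from petvalid.errors import ConfigurationError, CriteriaError

T0 = datetime(2025, 1, 15, 10, 0, tzinfo=timezone.utc)


def _cal_result(bias: float) -> pv.CalibrationResult:
    df = pd.DataFrame({"slice_index": [10, 11], "mean_bq_ml": [bias * 5000.0] * 2, "bias": [bias] * 2})
    return pv.CalibrationResult(
        per_slice=df,
        global_bias=bias,
        axial_uniformity=0.0,
        roi_diameter_mm=180.0,
        slices_used=(10, 11),
        a_bkg_kbq_ml=5.0,
        acquisition_start=T0,
        radionuclide="F-18",
    )


def _curve(values: dict[float, float], extra: dict[float, float] | None = None) -> pv.RecoveryCurve:
    diameters = list(values) + list(extra or {})
    crc_max = list(values.values()) + list((extra or {}).values())
    rows = pd.DataFrame(
        {
            "diameter_mm": diameters,
            "crc_max": crc_max,
            "crc_mean": crc_max,
            "crc_peak": crc_max,
            "rc_max": crc_max,
            "rc_mean": crc_max,
            "rc_peak": crc_max,
            "informational": [False] * len(values) + [True] * len(extra or {}),
        }
    )
    return pv.RecoveryCurve(
        contrast=8.0,
        calibration_bias=1.0,
        rows=rows,
        c_bkg_bq_ml=2000.0,
        a_bkg_kbq_ml=2.0,
        a_sphere_kbq_ml=16.0,
        acquisition_start=T0,
        radionuclide="F-18",
    )


MIDPOINTS = {10.0: 0.655, 13.0: 1.04, 17.0: 1.215, 22.0: 1.19, 28.0: 1.155, 37.0: 1.195}


class TestEvaluateCalibration:
    @pytest.mark.parametrize(
        "nuclide, tier, bias, expect_pass",
        [
            ("F-18", 1, 1.05, True),   # boundary inclusive
            ("F-18", 1, 1.06, False),
            ("F-18", 1, 0.95, True),
            ("Zr-89", 1, 1.08, True),  # wider tolerance for other nuclides
            ("Zr-89", 1, 1.11, False),
            ("F-18", 2, 1.08, True),   # tier 2 relaxes F-18 to 10%
        ],
    )
    def test_tier_tolerances(self, nuclide, tier, bias, expect_pass):
        decision = pv.evaluate_calibration(_cal_result(bias), nuclide, tier)
        assert decision.passed is expect_pass

    def test_strict_mode_excludes_boundary(self):
        crit = pv.CalibrationCriteria.from_config(1, strict=True)
        decision = pv.evaluate_calibration(_cal_result(1.05), "F-18", 1, criteria=crit)
        assert not decision.passed

    def test_unknown_nuclide_names_registry(self):
        with pytest.raises(ConfigurationError, match="F-18"):
            pv.evaluate_calibration(_cal_result(1.0), "Xx-99", 1)

    def test_tightening_never_converts_fail_to_pass(self):
        """Monotonicity: decisions only get stricter as the tolerance shrinks."""
        bias = 1.047
        verdicts = []
        for tol in np.arange(0.01, 0.11, 0.005):
            crit = pv.CalibrationCriteria(
                tier=1, tolerance_by_nuclide={"default": float(tol)}, frequency_by_nuclide={}
            )
            verdicts.append(pv.evaluate_calibration(_cal_result(bias), "F-18", 1, criteria=crit).passed)
        # once passing at some tolerance, passing at every larger tolerance
        first_pass = verdicts.index(True)
        assert all(verdicts[first_pass:])
        assert not any(verdicts[:first_pass])


class TestEvaluateCrc:
    def test_midpoints_pass(self):
        assert pv.evaluate_crc(_curve(MIDPOINTS)).passed

    def test_low_10mm_fails(self):
        vals = {**MIDPOINTS, 10.0: 0.44}
        decision = pv.evaluate_crc(_curve(vals))
        assert not decision.passed
        item = next(f for f in decision.findings if "10mm" in f.item)
        assert item.verdict == "fail"

    def test_high_37mm_fails(self):
        vals = {**MIDPOINTS, 37.0: 1.34}
        assert not pv.evaluate_crc(_curve(vals)).passed

    def test_boundaries_inclusive(self):
        assert pv.evaluate_crc(_curve({**MIDPOINTS, 10.0: 0.45})).passed
        assert pv.evaluate_crc(_curve({**MIDPOINTS, 37.0: 1.33})).passed

    def test_7mm_sphere_reported_not_judged(self):
        decision = pv.evaluate_crc(_curve(MIDPOINTS, extra={7.0: 0.2}))
        assert decision.passed
        info = next(f for f in decision.findings if f.item == "crc_max_7mm")
        assert info.verdict == "informational"

    def test_missing_mandated_diameter_rejected(self):
        vals = {d: v for d, v in MIDPOINTS.items() if d != 17.0}
        with pytest.raises(CriteriaError, match="17"):
            pv.evaluate_crc(_curve(vals))

    def test_decisions_are_deterministic(self):
        a = decision_to_json(pv.evaluate_crc(_curve(MIDPOINTS)))
        b = decision_to_json(pv.evaluate_crc(_curve(MIDPOINTS)))
        assert a == b


class TestValidityWindows:
    @pytest.mark.parametrize(
        "nuclide, purpose, expected_until",
        [
            ("F-18", "calibration", date(2025, 4, 15)),
            ("Ga-68", "calibration", date(2025, 4, 15)),
            ("Zr-89", "calibration", date(2026, 1, 15)),
            ("F-18", "recovery", date(2026, 1, 15)),
        ],
    )
    def test_windows(self, nuclide, purpose, expected_until):
        valid_from, valid_until = pv.validity_window(date(2025, 1, 15), nuclide, purpose)
        assert valid_from == date(2025, 1, 15)
        assert valid_until == expected_until

    def test_month_end_clamped(self):
        _, until = pv.validity_window(date(2025, 1, 31), "F-18", "calibration")
        assert until == date(2025, 4, 30)

    def test_unknown_purpose_rejected(self):
        with pytest.raises(CriteriaError):
            pv.validity_window(date(2025, 1, 15), "F-18", "weekly")


class TestApplyEvents:
    def _decision(self):
        return pv.evaluate_calibration(_cal_result(1.0), "F-18", 1)

    def test_trigger_truncates_window(self):
        d = self._decision()
        out = pv.apply_events(d, [{"date": "2025-02-01", "kind": "software_update"}])
        assert out.valid_until == date(2025, 2, 1)

    def test_event_before_window_ignored(self):
        d = self._decision()
        out = pv.apply_events(d, [{"date": "2024-12-01", "kind": "software_update"}])
        assert out.valid_until == d.valid_until

    def test_unrelated_kind_ignored(self):
        d = self._decision()
        out = pv.apply_events(d, [{"date": "2025-02-01", "kind": "room_repainted"}])
        assert out.valid_until == d.valid_until

    def test_earliest_trigger_wins(self):
        d = self._decision()
        out = pv.apply_events(
            d,
            [
                {"date": "2025-03-01", "kind": "major_service"},
                {"date": "2025-02-01", "kind": "calibrator_service"},
            ],
        )
        assert out.valid_until == date(2025, 2, 1)


class TestDecisionRecord:
    def test_inconsistent_pass_flag_rejected(self):
        with pytest.raises(CriteriaError):
            ValidationDecision(
                subject="calibration",
                passed=True,
                findings=(Finding("x", 1.2, "≤ 1.05", "fail"),),
                valid_from=date(2025, 1, 15),
                valid_until=date(2025, 4, 15),
            )

    def test_empty_window_rejected(self):
        with pytest.raises(CriteriaError):
            ValidationDecision(
                subject="calibration",
                passed=True,
                findings=(),
                valid_from=date(2025, 1, 15),
                valid_until=date(2025, 1, 15),
            )

    def test_markdown_report_mentions_pending_review(self):
        md = decision_to_markdown(pv.evaluate_calibration(_cal_result(1.0), "F-18", 1))
        assert "PENDING" in md
        assert "PASS" in md

    def test_crc_criteria_config_well_formed(self):
        crit = CrcCriteria.from_config()
        assert set(crit.limits) == {10.0, 13.0, 17.0, 22.0, 28.0, 37.0}
        assert all(lo < hi for lo, hi in crit.limits.values())
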