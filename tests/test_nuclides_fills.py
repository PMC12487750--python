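"""Decay correction, fill accounting and fill QC."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petvalid as pv
from petvalid.errors import ConfigurationError, FillRecordError
from petvalid.fills import (
    QcLimits,
    clock_sync_flags,
    fill_from_dict,
    fill_to_dict,
    read_assays_csv,
)

T0 = datetime(2025, 1, 15, 8, 0, tzinfo=timezone.utc)
CU64 = pv.get_nuclide("Cu-64")


def _fill(pre_mbq, post_mbq, volume_ml=9250.0, nuclide=CU64, kind="background"):
    return pv.FillRecord(
        radionuclide=nuclide,
        pre_assay=pv.ActivityAssay(pre_mbq, T0, "calA"),
        post_assay=pv.ActivityAssay(post_mbq, T0, "calA"),
        fill_time=T0,
        compartment_volume_ml=volume_ml,
        compartment_kind=kind,
    )


class TestDecay:
    @pytest.mark.parametrize(
        "hours, expected",
        [(0.0, 100.0), (12.7, 50.0), (25.4, 25.0)],
    )
    def test_half_life_halving(self, hours, expected):
        out = pv.decay_correct(100.0, T0, T0 + timedelta(hours=hours), CU64)
        assert out == pytest.approx(expected, rel=1e-12)

    def test_backward_correction_is_inverse(self):
        t1 = T0 + timedelta(hours=5)
        fwd = pv.decay_correct(80.0, T0, t1, CU64)
        assert pv.decay_correct(fwd, t1, T0, CU64) == pytest.approx(80.0, rel=1e-12)

    @given(
        activity=st.floats(0.01, 1e4),
        dt_half_lives=st.floats(-30, 30),
        half_life=st.floats(1.0, 1e4),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_property(self, activity, dt_half_lives, half_life):
        nuc = pv.Radionuclide("X", half_life)
        t1 = T0 + timedelta(minutes=dt_half_lives * half_life)
        there = pv.decay_correct(activity, T0, t1, nuc)
        back = pv.decay_correct(there, t1, T0, nuc)
        assert back == pytest.approx(activity, rel=1e-12)

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ConfigurationError):
            pv.Radionuclide("bad", 0.0)

    @pytest.mark.parametrize("alias", ["F18", "f-18", "ga68", "CU64", "Zr-89", "I_124"])
    def test_registry_alias_lookup(self, alias):
        assert pv.get_nuclide(alias).half_life_min > 0

    def test_unknown_nuclide_names_registry(self):
        with pytest.raises(ConfigurationError, match="F-18"):
            pv.get_nuclide("Tc-99m")


class TestFillAccounting:
    def test_net_activity_no_decay(self):
        assert pv.net_activity_at(_fill(200.0, 10.0), T0) == pytest.approx(190.0)

    def test_net_activity_one_half_life(self):
        out = pv.net_activity_at(_fill(200.0, 10.0), T0 + timedelta(hours=12.7))
        assert out == pytest.approx(95.0, rel=1e-12)

    def test_residual_exceeding_pre_rejected(self):
        with pytest.raises(FillRecordError):
            _fill(10.0, 200.0)

    @given(dt_min=st.floats(-2000, 2000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reference_time_invariance(self, dt_min):
        """Correcting assays via any intermediate time equals direct correction."""
        fill = _fill(200.0, 10.0)
        target = T0 + timedelta(hours=30)
        mid = T0 + timedelta(minutes=dt_min)
        direct = pv.net_activity_at(fill, target)
        via_mid = pv.decay_correct(pv.net_activity_at(fill, mid), mid, target, CU64)
        assert via_mid == pytest.approx(direct, rel=1e-10)

    @pytest.mark.parametrize(
        "gross, empty, density, expected",
        [(2000.0, 1000.0, 1.0, 1000.0), (11197.0, 1999.0, 0.9982, 9214.5863)],
    )
    def test_volume_from_weight(self, gross, empty, density, expected):
        assert pv.volume_from_weight(gross, empty, density) == pytest.approx(expected, abs=1e-3)

    def test_volume_from_weight_rejects_empty_net(self):
        with pytest.raises(FillRecordError):
            pv.volume_from_weight(1000.0, 1000.0)

    def test_concentration_at(self):
        # 37 MBq in 9250 mL at reference time -> 4.0 kBq/mL
        assert pv.concentration_at(_fill(37.0, 0.0), T0) == pytest.approx(4.0, rel=1e-12)

    def test_concentration_zero_net(self):
        assert pv.concentration_at(_fill(5.0, 5.0), T0) == 0.0

    @given(scale=st.floats(0.1, 10), vol=st.floats(100, 20000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_concentration_scaling_property(self, scale, vol):
        """Concentration is linear in net activity, inverse in volume."""
        base = pv.concentration_at(_fill(100.0, 0.0, volume_ml=vol), T0)
        scaled = pv.concentration_at(_fill(100.0 * scale, 0.0, volume_ml=vol), T0)
        assert scaled == pytest.approx(base * scale, rel=1e-12)
        halved_vol = pv.concentration_at(_fill(100.0, 0.0, volume_ml=vol / 2), T0)
        assert halved_vol == pytest.approx(base * 2, rel=1e-12)


class TestContrastAndPlanning:
    @pytest.mark.parametrize("sph, bkg, expected", [(16, 2, 8), (2, 2, 1), (0, 2, 0)])
    def test_achieved_contrast(self, sph, bkg, expected):
        assert pv.achieved_contrast(sph, bkg) == pytest.approx(expected)

    def test_zero_background_rejected(self):
        with pytest.raises(FillRecordError):
            pv.achieved_contrast(16, 0)

    def test_plan_recommended_fill(self):
        plan = pv.plan_rc_fill(2.0)
        assert plan["sphere_conc_kbq_ml"] == pytest.approx(16.0)
        assert pv.achieved_contrast(plan["sphere_conc_kbq_ml"], plan["bkg_conc_kbq_ml"]) == 8.0


class TestFillQc:
    def test_recommended_rc_plan_clean(self):
        flags = pv.fill_qc(
            {"scan_kind": "rc", "bkg_conc_kbq_ml": 2.0, "contrast": 8.0, "total_activity_in_fov_mbq": 20.0}
        )
        assert flags == []

    def test_rc_background_cap(self):
        flags = pv.fill_qc({"scan_kind": "rc", "bkg_conc_kbq_ml": 6.5})
        assert any(f.code == "rc_bkg_exceeds_limit" for f in flags)
        assert pv.fill_qc({"scan_kind": "rc", "bkg_conc_kbq_ml": 6.0}) == []

    def test_calibration_background_range(self):
        assert pv.fill_qc({"scan_kind": "calibration", "bkg_conc_kbq_ml": 5.0}) == []
        flags = pv.fill_qc({"scan_kind": "calibration", "bkg_conc_kbq_ml": 2.5})
        assert any(f.code == "calibration_bkg_range" for f in flags)

    def test_fov_activity_warning(self):
        flags = pv.fill_qc({"scan_kind": "rc", "total_activity_in_fov_mbq": 45.0})
        assert any(f.code == "fov_activity_dead_time" for f in flags)
        assert pv.fill_qc({"scan_kind": "rc", "total_activity_in_fov_mbq": 39.0}) == []

    def test_contrast_deviation_flag(self):
        flags = pv.fill_qc({"scan_kind": "rc", "contrast": 6.0})
        assert any(f.code == "contrast_deviation" for f in flags)

    def test_qc_never_raises_on_sparse_plan(self):
        assert pv.fill_qc({}) == []

    def test_clock_offset_flagging(self):
        fill = pv.FillRecord(
            radionuclide=CU64,
            pre_assay=pv.ActivityAssay(100.0, T0, "calA", clock_offset_s=90.0),
            post_assay=pv.ActivityAssay(5.0, T0, "calA", clock_offset_s=30.0),
            fill_time=T0,
            compartment_volume_ml=1000.0,
        )
        flags = clock_sync_flags(fill)
        assert len(flags) == 1 and "pre_assay" in flags[0].message


class TestSerialization:
    def test_fill_json_round_trip(self):
        fill = _fill(200.0, 10.0, kind="sphere_stock")
        again = fill_from_dict(fill_to_dict(fill))
        assert again == fill

    def test_assay_csv_import(self, tmp_path):
        p = tmp_path / "assays.csv"
        p.write_text(
            "activity_mbq,assay_time,device_id,clock_offset_s\n"
            "203.5,2025-01-15T08:00:00+00:00,calA,12\n"
            "10.1,2025-01-15T08:05:00+00:00,calA,12\n"
        )
        assays = read_assays_csv(p)
        assert [a.activity_mbq for a in assays] == [203.5, 10.1]
        assert assays[0].assay_time == T0
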