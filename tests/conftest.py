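"""Shared fixtures: synthetic phantom scans generated once per session."""

from __future__ import annotations

import pytest

import petvalid as pv


@pytest.fixture(scope="session")
def rc_fixture():
    """Noise-free recovery fixture: iq_nema, 2 kBq/mL background, 8:1, FWHM 5 mm."""
    fx = pv.make_fixture("rc_annual")
    fx["fills_by_kind"] = {f.compartment_kind: f for f in fx["fills"]}
    return fx


@pytest.fixture(scope="session")
def rc_curve(rc_fixture):
    """Recovery curve measured from the noise-free fixture (2× spline supersampling)."""
    return pv.analyze_recovery(
        rc_fixture["simulated"],
        rc_fixture["fills_by_kind"],
        rc_fixture["phantom"],
        supersampling=2,
    )


@pytest.fixture(scope="session")
def cal_fixture():
    """Noise-free calibration fixture: uniform20 at 5 kBq/mL, unit bias."""
    return pv.make_fixture("calibration_quarterly")
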