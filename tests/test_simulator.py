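"""Ground-truth rasterization, scan simulation and the analytic recovery oracle."""

from __future__ import annotations

import math
from datetime import datetime, timezone

import numpy as np
import pytest

import petvalid as pv
from petvalid.errors import ConfigurationError
from petvalid.phantoms import ColdInsert, SphereInsert
from petvalid.simulate import predicted_voi_mean_rc

T0 = datetime(2025, 1, 15, 10, 0, tzinfo=timezone.utc)

# Independent fine-grid 3-D convolution oracle (ball rasterized at 0.25 mm,
# Gaussian blur, mean over the ball), computed once with scipy.ndimage and
# frozen here; checks the closed-form radial-quadrature implementation.
BRUTE_MEAN_RC_FWHM5 = {
    10.0: 0.521929,
    13.0: 0.622871,
    17.0: 0.707246,
    22.0: 0.771865,
    28.0: 0.819895,
    37.0: 0.863276,
}
BRUTE_MEAN_RC_37_FWHM1 = 0.972573


def _one_sphere_phantom(diameter=22.0):
    return pv.PhantomSpec(
        name="one-sphere",
        kind="torso_iq",
        body_volume_l=4.0,
        axial_length_mm=120.0,
        body_shape="noncylindrical",
        spheres=(SphereInsert(diameter, (30.0, 0.0, 0.0)),),
        body_semi_axes_mm=(80.0, 60.0),
    )


class TestRasterize:
    def test_compartment_values(self):
        spec = _one_sphere_phantom()
        vol = pv.rasterize_phantom(spec, 2.0, 16.0, spacing_mm=2.0, supersampling=2)
        idx_center = tuple(
            int(round((c - o) / s))
            for c, o, s in zip((30.0, 0.0, 0.0), vol.origin_mm, vol.spacing_mm)
        )
        assert vol.voxels[idx_center] == pytest.approx(16000.0)  # sphere interior
        idx_bkg = tuple(
            int(round((c - o) / s))
            for c, o, s in zip((-40.0, 0.0, 0.0), vol.origin_mm, vol.spacing_mm)
        )
        assert vol.voxels[idx_bkg] == pytest.approx(2000.0)  # background
        assert vol.voxels[0, 0, 0] == 0.0  # exterior corner

    def test_cold_insert_painted_zero(self):
        spec = pv.builtin_phantom("iq_nema")
        vol = pv.rasterize_phantom(spec, 2.0, 16.0, spacing_mm=2.0, supersampling=2)
        idx = tuple(int(round((0.0 - o) / s)) for o, s in zip(vol.origin_mm, vol.spacing_mm))
        assert vol.voxels[idx] == 0.0

    @pytest.mark.parametrize("diameter", [10.0, 22.0, 37.0])
    def test_painted_sphere_activity_matches_analytic_volume(self, diameter):
        """Total painted excess equals (sphere − bkg) × (π/6)d³ within 0.5% at 4× sampling."""
        spec = _one_sphere_phantom(diameter)
        hot = pv.rasterize_phantom(spec, 2.0, 16.0, spacing_mm=2.0, supersampling=4)
        flat = pv.rasterize_phantom(spec, 2.0, 2.0, spacing_mm=2.0, supersampling=4)
        excess_bq = (hot.voxels - flat.voxels).sum() * hot.voxel_volume_ml
        expected = (16000.0 - 2000.0) * math.pi / 6.0 * diameter**3 / 1000.0
        assert excess_bq == pytest.approx(expected, rel=5e-3)

    def test_phantom_exceeding_grid_rejected(self):
        spec = _one_sphere_phantom()
        with pytest.raises(ConfigurationError):
            pv.rasterize_phantom(
                spec, 2.0, 16.0, spacing_mm=2.0, shape=(20, 20, 20), origin_mm=(-20.0, -20.0, -20.0)
            )


class TestSimulateScan:
    def _truth(self):
        return pv.rasterize_phantom(_one_sphere_phantom(), 2.0, 16.0, spacing_mm=2.0, supersampling=2)

    def test_identity_when_disabled(self):
        truth = self._truth()
        out = pv.simulate_scan(truth, pv.SimulationConfig(psf_fwhm_mm=0.0))
        assert np.array_equal(out.voxels, truth.voxels)

    def test_same_seed_bit_identical(self):
        truth = self._truth()
        cfg = pv.SimulationConfig(psf_fwhm_mm=5.0, noise_sigma0=100.0, seed=42)
        a = pv.simulate_scan(truth, cfg)
        b = pv.simulate_scan(truth, cfg)
        assert np.array_equal(a.voxels, b.voxels)

    def test_different_seed_differs(self):
        truth = self._truth()
        a = pv.simulate_scan(truth, pv.SimulationConfig(noise_sigma0=100.0, seed=1))
        b = pv.simulate_scan(truth, pv.SimulationConfig(noise_sigma0=100.0, seed=2))
        assert not np.array_equal(a.voxels, b.voxels)

    def test_bias_is_pure_scaling(self):
        truth = self._truth()
        ref = pv.simulate_scan(truth, pv.SimulationConfig(psf_fwhm_mm=5.0))
        biased = pv.simulate_scan(truth, pv.SimulationConfig(psf_fwhm_mm=5.0, calibration_bias=1.04))
        assert np.allclose(biased.voxels, 1.04 * ref.voxels, rtol=1e-12)

    def test_blur_conserves_activity(self):
        truth = self._truth()
        out = pv.simulate_scan(truth, pv.SimulationConfig(psf_fwhm_mm=5.0))
        assert out.voxels.sum() == pytest.approx(truth.voxels.sum(), rel=1e-3)

    def test_noise_realization_mean_converges(self):
        """Law of large numbers: the N-average approaches the noise-free image."""
        truth = self._truth()
        clean = pv.simulate_scan(truth, pv.SimulationConfig(psf_fwhm_mm=5.0))
        n = 50
        sigma0 = 200.0
        acc = np.zeros_like(clean.voxels)
        for seed in range(n):
            acc += pv.simulate_scan(
                truth, pv.SimulationConfig(psf_fwhm_mm=5.0, noise_sigma0=sigma0, seed=seed)
            ).voxels
        acc /= n
        core = clean.voxels > 1500.0  # interior voxels with non-trivial signal
        sigma_vox = sigma0 * np.sqrt(clean.voxels[core] / 2000.0)
        resid = acc[core] - clean.voxels[core]
        assert np.all(np.abs(resid) <= 5.0 * sigma_vox / math.sqrt(n))
        assert abs(resid.mean()) <= 3.0 * sigma_vox.mean() / math.sqrt(n * core.sum())


class TestAnalyticOracle:
    def test_no_blur_limit(self):
        assert pv.analytic_sphere_mean_rc(37.0, 0.0) == 1.0

    def test_vanishing_sphere_limit(self):
        assert pv.analytic_sphere_mean_rc(0.5, 5.0) < 0.01

    def test_monotone_in_diameter(self):
        vals = [pv.analytic_sphere_mean_rc(d, 5.0) for d in (10, 13, 17, 22, 28, 37)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("diameter, expected", sorted(BRUTE_MEAN_RC_FWHM5.items()))
    def test_matches_fine_grid_convolution_oracle(self, diameter, expected):
        assert pv.analytic_sphere_mean_rc(diameter, 5.0) == pytest.approx(expected, rel=2.5e-3)

    def test_matches_oracle_at_narrow_psf(self):
        assert pv.analytic_sphere_mean_rc(37.0, 1.0) == pytest.approx(
            BRUTE_MEAN_RC_37_FWHM1, rel=2.5e-3
        )

    def test_voxel_aperture_reduces_prediction(self):
        pure = predicted_voi_mean_rc(10.0, 5.0, voxel_mm=0.0)
        assert pure == pytest.approx(pv.analytic_sphere_mean_rc(10.0, 5.0), rel=1e-12)
        assert predicted_voi_mean_rc(10.0, 5.0, voxel_mm=2.0) < pure


class TestFixtures:
    def test_calibration_defaults(self, cal_fixture):
        m = cal_fixture["manifest"]
        assert m["phantom"] == "uniform20"
        assert m["bkg_conc_kbq_ml"] == 5.0
        assert m["injected_bias"] == 1.0

    def test_rc_defaults(self, rc_fixture):
        m = rc_fixture["manifest"]
        assert m["phantom"] == "iq_nema"
        assert m["bkg_conc_kbq_ml"] == 2.0
        assert m["contrast"] == 8.0
        assert m["sphere_conc_kbq_ml"] == pytest.approx(16.0)

    def test_override_recorded_in_manifest(self):
        fx = pv.make_fixture(
            "calibration_quarterly", {"calibration_bias": 1.06, "spacing_mm": 4.0}
        )
        assert fx["manifest"]["injected_bias"] == 1.06

    def test_fixture_fills_reproduce_target_concentration(self, rc_fixture):
        t = rc_fixture["simulated"].acquisition_start
        by_kind = rc_fixture["fills_by_kind"]
        assert pv.concentration_at(by_kind["background"], t) == pytest.approx(2.0, rel=1e-9)
        assert pv.concentration_at(by_kind["sphere_stock"], t) == pytest.approx(16.0, rel=1e-9)

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ConfigurationError):
            pv.make_fixture("weekly_special")
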