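"""Sphere VOI statistics and contrast-recovery-coefficient analysis.

For the *i*-th hot sphere with measured concentration C_sphere(i), measured
background C_bkg, and assay-derived true concentrations A_sphere and A_bkg:

    CRC_i = ((C_sphere(i) − C_bkg) / C_bkg) / ((A_sphere − A_bkg) / A_bkg)
    RC_i  = C_sphere(i) / A_sphere
    CRC_i = (RC_i × contrast / calibration_bias − 1) / (contrast − 1)

with contrast = A_sphere/A_bkg and calibration_bias = C_bkg/A_bkg.  CRC is
invariant to scanner calibration bias (numerator and denominator of the
measured contrast scale together); RC scales linearly with it.

VOI conventions:

* the measurement VOI is a sphere of the *exact inner diameter* of the
  insert, centered on the intensity-weighted centroid of the PET signal
  (CT-based placement is deliberately not offered: PET/CT coregistration
  errors of a couple of millimetres would corrupt mean measurements);
* C_mean averages voxels whose centers fall inside that VOI; C_max is the
  maximum voxel in it (first-in-scan-order tie-break);
* C_peak is the highest mean of a 1-cm³ sphere (diameter ≈ 12.407 mm)
  whose center lies inside the exact-size VOI, searched on a half-voxel
  lattice.

An optional supersampling factor (2× per axis, trilinear) can be applied to
the local neighbourhood before extraction; whether software supersamples
before calculation is a known source of inter-package differences, so the
factor used is recorded in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
from scipy.ndimage import zoom as ndi_zoom
from scipy.signal import fftconvolve

from .errors import AnalysisError, DetectionError
from .fills import FillRecord, concentration_at
from .imaging import ImageVolume
from .phantoms import PhantomSpec

__all__ = [
    "SphereMeasurement",
    "RecoveryCurve",
    "locate_sphere_centroid",
    "sphere_voi_stats",
    "crc",
    "rc",
    "rc_to_crc",
    "crc_to_rc",
    "peak_sphere_diameter_mm",
    "default_background_rois",
    "analyze_recovery",
]


def peak_sphere_diameter_mm(peak_volume_ml: float = 1.0) -> float:
    """Diameter of the peak-VOI sphere; ≈ 12.407 mm for the standard 1 cm³."""
    return (6000.0 * peak_volume_ml / math.pi) ** (1.0 / 3.0)


@dataclass
class SphereMeasurement:
    """Measured concentrations (Bq/mL) for one sphere insert."""

    nominal_diameter_mm: float
    center_estimate_mm: tuple[float, float, float]
    c_mean: float
    c_max: float
    c_peak: float
    n_voxels: int
    supersampling: int = 1


@dataclass
class RecoveryCurve:
    """CRC/RC curve for one phantom acquisition, all three VOI metrics."""

    contrast: float  # A_sphere / A_bkg (fill-derived, not nominal)
    calibration_bias: float  # C_bkg / A_bkg
    rows: pd.DataFrame  # diameter_mm, crc_max, crc_mean, crc_peak, rc_max, rc_mean, rc_peak
    c_bkg_bq_ml: float
    a_bkg_kbq_ml: float
    a_sphere_kbq_ml: float
    acquisition_start: datetime
    radionuclide: str
    supersampling: int = 1
    flags: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "calibration_bias": self.calibration_bias,
            "c_bkg_bq_ml": self.c_bkg_bq_ml,
            "a_bkg_kbq_ml": self.a_bkg_kbq_ml,
            "a_sphere_kbq_ml": self.a_sphere_kbq_ml,
            "acquisition_start": self.acquisition_start.isoformat(),
            "radionuclide": self.radionuclide,
            "supersampling": self.supersampling,
            "flags": list(self.flags),
            "rows": self.rows.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# elementary metrics

def crc(c_sphere: float, c_bkg: float, a_sphere: float, a_bkg: float) -> float:
    """Contrast recovery coefficient (measured contrast over true contrast)."""
    if not c_bkg > 0:
        raise AnalysisError(f"measured background must be positive, got {c_bkg}")
    if not a_bkg > 0 or a_sphere == a_bkg:
        raise AnalysisError("true concentrations must satisfy a_bkg > 0 and a_sphere != a_bkg")
    return ((c_sphere - c_bkg) / c_bkg) / ((a_sphere - a_bkg) / a_bkg)


def rc(c_sphere: float, a_sphere: float) -> float:
    """Recovery coefficient: measured over true sphere concentration."""
    if not a_sphere > 0:
        raise AnalysisError(f"true sphere concentration must be positive, got {a_sphere}")
    return c_sphere / a_sphere


def rc_to_crc(rc_value: float, contrast: float, calibration_bias: float) -> float:
    """Convert RC to CRC given the contrast and the scanner calibration bias."""
    if not contrast > 1:
        raise AnalysisError(f"contrast must exceed 1, got {contrast}")
    if not calibration_bias > 0:
        raise AnalysisError(f"calibration bias must be positive, got {calibration_bias}")
    return (rc_value * contrast / calibration_bias - 1.0) / (contrast - 1.0)


def crc_to_rc(crc_value: float, contrast: float, calibration_bias: float) -> float:
    """Inverse of :func:`rc_to_crc` (exact algebraic inverse)."""
    if not contrast > 1:
        raise AnalysisError(f"contrast must exceed 1, got {contrast}")
    if not calibration_bias > 0:
        raise AnalysisError(f"calibration bias must be positive, got {calibration_bias}")
    return (crc_value * (contrast - 1.0) + 1.0) * calibration_bias / contrast


# ---------------------------------------------------------------------------
# VOI machinery

def _voxel_center_grids(volume: ImageVolume, box: tuple[slice, slice, slice]):
    xs = volume.axis_coords(0)[box[0]]
    ys = volume.axis_coords(1)[box[1]]
    zs = volume.axis_coords(2)[box[2]]
    return np.meshgrid(xs, ys, zs, indexing="ij")


def _box_around(volume: ImageVolume, center, radius_mm: float) -> tuple[slice, slice, slice]:
    sl = []
    for d in range(3):
        n = volume.shape[d]
        i0 = int(np.floor((center[d] - radius_mm - volume.origin_mm[d]) / volume.spacing_mm[d]))
        i1 = int(np.ceil((center[d] + radius_mm - volume.origin_mm[d]) / volume.spacing_mm[d])) + 1
        sl.append(slice(max(0, i0), min(n, i1)))
    return tuple(sl)  # type: ignore[return-value]


def locate_sphere_centroid(
    volume: ImageVolume,
    seed_center_mm: tuple[float, float, float],
    nominal_diameter_mm: float,
    background_bq_ml: float | None = None,
    max_iter: int = 20,
    tol_mm: float = 0.01,
) -> tuple[float, float, float]:
    """Iterated intensity-weighted centroid of the background-subtracted signal.

    The search ball has radius ``nominal_diameter`` around the current
    center.  If no background estimate is supplied, the median of the
    initial search ball is used (the ball is ≥ 8× the sphere volume, so the
    median sits in background).  Raises :class:`DetectionError` when no
    voxel rises meaningfully above background.
    """
    lo, hi = volume.world_extent()
    seed = np.asarray(seed_center_mm, dtype=np.float64)
    if np.any(seed < lo) or np.any(seed > hi):
        raise AnalysisError("seed center lies outside the image grid")
    search_r = nominal_diameter_mm

    box = _box_around(volume, seed, search_r)
    X, Y, Z = _voxel_center_grids(volume, box)
    vals0 = volume.voxels[box]
    in_ball0 = (X - seed[0]) ** 2 + (Y - seed[1]) ** 2 + (Z - seed[2]) ** 2 <= search_r**2
    if not in_ball0.any():
        raise DetectionError("search ball contains no voxels")
    bkg = float(np.median(vals0[in_ball0])) if background_bq_ml is None else float(background_bq_ml)

    vmax = float(vals0[in_ball0].max())
    scale = max(abs(vmax), abs(bkg), 1e-30)
    if vmax - bkg <= 0.1 * abs(bkg) + 1e-9 * scale:
        raise DetectionError(
            f"no signal above background ({bkg:.4g} Bq/mL) in the search ball"
        )

    center = seed.copy()
    for _ in range(max_iter):
        box = _box_around(volume, center, search_r)
        X, Y, Z = _voxel_center_grids(volume, box)
        vals = volume.voxels[box]
        in_ball = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= search_r**2
        w = np.clip(vals - bkg, 0.0, None) * in_ball
        tot = w.sum()
        if tot <= 0:
            raise DetectionError("no positive background-subtracted signal in the search ball")
        new = np.array([(w * X).sum(), (w * Y).sum(), (w * Z).sum()]) / tot
        shift = float(np.linalg.norm(new - center))
        center = new
        if shift < tol_mm:
            break
    return tuple(center)  # type: ignore[return-value]


def _supersample_local(
    volume: ImageVolume, box: tuple[slice, slice, slice], factor: int
) -> ImageVolume:
    """Cubic-spline supersampling of a local subvolume (metadata adjusted).

    Spline interpolation adds essentially no further smoothing, unlike
    trilinear resampling, so the only resolution loss in the chain remains
    the acquisition voxel aperture itself.
    """
    sub = volume.voxels[box]
    fine = ndi_zoom(sub, factor, order=3, grid_mode=True, mode="nearest")
    spacing = tuple(s / factor for s in volume.spacing_mm)
    origin = tuple(
        volume.origin_mm[d]
        + volume.spacing_mm[d] * box[d].start
        - volume.spacing_mm[d] / 2.0
        + spacing[d] / 2.0
        for d in range(3)
    )
    return ImageVolume(
        voxels=fine,
        spacing_mm=spacing,  # type: ignore[arg-type]
        origin_mm=origin,  # type: ignore[arg-type]
        acquisition_start=volume.acquisition_start,
        radionuclide=volume.radionuclide,
    )


def _peak_mean(
    vol: ImageVolume,
    box: tuple[slice, slice, slice],
    voi_center,
    voi_radius_mm: float,
    peak_radius_mm: float,
) -> float:
    """Highest mean of a peak-radius sphere centered on a half-voxel lattice in the VOI.

    For each of the 8 half-voxel sublattice offsets the sphere mean at every
    candidate is a correlation of the image with a fixed binary kernel, so
    the search is 8 FFT convolutions over the local box.
    """
    sub = vol.voxels[box]
    spacing = np.asarray(vol.spacing_mm)
    xs = vol.axis_coords(0)[box[0]]
    ys = vol.axis_coords(1)[box[1]]
    zs = vol.axis_coords(2)[box[2]]
    voi_center = np.asarray(voi_center)

    best = -np.inf
    kmax = [int(np.ceil(peak_radius_mm / spacing[d])) + 1 for d in range(3)]
    for dx in (0.0, 0.5):
        for dy in (0.0, 0.5):
            for dz in (0.0, 0.5):
                delta = np.array([dx, dy, dz])
                # kernel over integer offsets k: voxel at X_i+k belongs to the
                # peak sphere centered at X_i + delta*spacing
                axes = [np.arange(-kmax[d], kmax[d] + 1) for d in range(3)]
                KX, KY, KZ = np.meshgrid(*axes, indexing="ij")
                dist2 = (
                    ((KX - delta[0]) * spacing[0]) ** 2
                    + ((KY - delta[1]) * spacing[1]) ** 2
                    + ((KZ - delta[2]) * spacing[2]) ** 2
                )
                kernel = (dist2 <= peak_radius_mm**2).astype(np.float64)
                count = kernel.sum()
                if count == 0:
                    continue
                # correlation = convolution with flipped kernel
                means = fftconvolve(sub, kernel[::-1, ::-1, ::-1] / count, mode="same")
                # candidate centers X_i + delta*spacing inside the exact VOI
                CX = xs[:, None, None] + delta[0] * spacing[0]
                CY = ys[None, :, None] + delta[1] * spacing[1]
                CZ = zs[None, None, :] + delta[2] * spacing[2]
                in_voi = (
                    (CX - voi_center[0]) ** 2
                    + (CY - voi_center[1]) ** 2
                    + (CZ - voi_center[2]) ** 2
                ) <= voi_radius_mm**2
                # exclude candidates whose peak sphere would leave the box
                # (their correlation would silently include zero padding)
                interior = np.zeros_like(in_voi)
                interior[
                    kmax[0] : sub.shape[0] - kmax[0] or None,
                    kmax[1] : sub.shape[1] - kmax[1] or None,
                    kmax[2] : sub.shape[2] - kmax[2] or None,
                ] = True
                ok = in_voi & interior
                if ok.any():
                    best = max(best, float(means[ok].max()))
    if not np.isfinite(best):
        raise AnalysisError("peak search found no valid candidate centers")
    return best


def sphere_voi_stats(
    volume: ImageVolume,
    center_mm: tuple[float, float, float],
    diameter_mm: float,
    peak_volume_ml: float = 1.0,
    supersampling: int = 1,
) -> SphereMeasurement:
    """Mean / max / peak concentration in an exact-size sphere VOI.

    ``supersampling`` > 1 trilinearly refines the local neighbourhood before
    extraction (2× per axis is the conventional choice).
    """
    r = diameter_mm / 2.0
    peak_r = peak_sphere_diameter_mm(peak_volume_ml) / 2.0
    pad = peak_r + 2.0 * max(volume.spacing_mm)
    lo, hi = volume.world_extent()
    c = np.asarray(center_mm, dtype=np.float64)
    if np.any(c - r < lo) or np.any(c + r > hi):
        raise AnalysisError("sphere VOI extends outside the image grid")

    work = volume
    box = _box_around(volume, c, r + pad)
    if supersampling > 1:
        work = _supersample_local(volume, box, supersampling)
        box = (slice(0, work.shape[0]), slice(0, work.shape[1]), slice(0, work.shape[2]))

    X, Y, Z = _voxel_center_grids(work, box)
    vals = work.voxels[box]
    in_voi = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r**2
    n = int(in_voi.sum())
    if n == 0:
        raise AnalysisError(
            f"no voxel centers inside the {diameter_mm:g}-mm VOI at this grid spacing; "
            "enable supersampling"
        )
    c_mean = float(vals[in_voi].mean())
    c_max = float(vals[in_voi].max())  # np.max scans in order; first occurrence wins ties
    c_peak = _peak_mean(work, box, c, r, peak_r)
    return SphereMeasurement(
        nominal_diameter_mm=diameter_mm,
        center_estimate_mm=tuple(c),
        c_mean=c_mean,
        c_max=c_max,
        c_peak=c_peak,
        n_voxels=n,
        supersampling=supersampling,
    )


# ---------------------------------------------------------------------------
# background sampling and full analysis

def default_background_rois(
    spec: PhantomSpec, roi_diameter_mm: float = 30.0, n_rois: int = 12
) -> list[tuple[float, float]]:
    """Deterministic background ROI centers (xy, mm) in the sphere plane.

    Circular 30-mm ROIs are placed in uniform background at the spheres'
    axial position: candidates on rings at increasing fractions of the body
    cross-section are accepted when they clear the wall (10 mm), any cold
    insert and every sphere (8-mm guard band), until ``n_rois`` are found.
    This is a documented convention, not a standard.
    """
    if spec.kind != "torso_iq":
        raise AnalysisError("background ROI placement requires a torso IQ phantom")
    a, b = spec.body_semi_axes_mm
    roi_r = roi_diameter_mm / 2.0
    wall_margin = 10.0
    guard = 8.0
    sphere_z = float(np.mean([s.center_mm[2] for s in spec.spheres]))

    out: list[tuple[float, float]] = []
    for frac in (0.50, 0.60, 0.70, 0.80, 0.90):
        for ang in range(0, 360, 15):
            t = math.radians(ang)
            p = (frac * a * math.cos(t), frac * b * math.sin(t))
            # inside the wall-eroded ellipse
            ea, eb = a - roi_r - wall_margin, b - roi_r - wall_margin
            if (p[0] / ea) ** 2 + (p[1] / eb) ** 2 > 1.0:
                continue
            # clear of cold inserts crossing the sphere plane
            clear = True
            for ins in spec.cold_inserts:
                z0, z1 = ins.z_range_mm or (
                    -spec.axial_length_mm / 2,
                    spec.axial_length_mm / 2,
                )
                if not z0 <= sphere_z <= z1:
                    continue
                d = math.hypot(p[0] - ins.center_xy_mm[0], p[1] - ins.center_xy_mm[1])
                if d < ins.diameter_mm / 2.0 + roi_r + guard:
                    clear = False
                    break
            if not clear:
                continue
            for s in spec.spheres:
                d = math.hypot(p[0] - s.center_mm[0], p[1] - s.center_mm[1])
                if d < s.inner_diameter_mm / 2.0 + roi_r + guard:
                    clear = False
                    break
            if not clear:
                continue
            if any(math.hypot(p[0] - q[0], p[1] - q[1]) < roi_diameter_mm for q in out):
                continue  # avoid heavy ROI overlap
            out.append(p)
            if len(out) >= n_rois:
                return out
    if not out:
        raise AnalysisError("could not place any background ROI in this phantom")
    return out


def _background_mean(
    volume: ImageVolume,
    rois_xy: list[tuple[float, float]],
    roi_diameter_mm: float,
    plane_z_mm: float,
) -> float:
    """Average of per-ROI means on the slice nearest ``plane_z_mm``."""
    zc = volume.axis_coords(2)
    k = int(np.argmin(np.abs(zc - plane_z_mm)))
    xs = volume.axis_coords(0)
    ys = volume.axis_coords(1)
    r = roi_diameter_mm / 2.0
    means = []
    for cx, cy in rois_xy:
        mask = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= r**2
        if not mask.any():
            raise AnalysisError("background ROI contains no voxel centers")
        means.append(float(volume.voxels[:, :, k][mask].mean()))
    return float(np.mean(means))


def analyze_recovery(
    volume: ImageVolume,
    fills: dict[str, FillRecord],
    spec: PhantomSpec,
    bkg_rois_xy: list[tuple[float, float]] | None = None,
    bkg_roi_diameter_mm: float = 30.0,
    peak_volume_ml: float = 1.0,
    supersampling: int = 1,
    criteria_diameters: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0),
) -> RecoveryCurve:
    """Measure every sphere and assemble the CRC/RC curve.

    ``fills`` maps ``"background"`` and ``"sphere_stock"`` to their fill
    records; both are decay-corrected to the volume's acquisition start.
    The contrast used in all conversions is the fill-derived true contrast
    A_sphere/A_bkg (the nominal 8:1 is a fill-QC matter, not an analysis
    input).  Spheres that cannot be detected are reported in ``flags`` and
    their row left as NaN.  Spheres whose diameter is not in
    ``criteria_diameters`` (e.g. a 7-mm insert) are marked informational.
    """
    if not spec.spheres:
        raise AnalysisError("phantom has no spheres to measure")
    if volume.units != "Bq/mL":
        raise AnalysisError("volume must be in Bq/mL")
    for key in ("background", "sphere_stock"):
        if key not in fills:
            raise AnalysisError(f"missing {key!r} fill record")
        if fills[key].radionuclide.name != volume.radionuclide:
            raise AnalysisError(f"{key} fill radionuclide does not match the volume")

    t = volume.acquisition_start
    a_bkg = concentration_at(fills["background"], t)
    a_sphere = concentration_at(fills["sphere_stock"], t)
    if not a_sphere > a_bkg:
        raise AnalysisError("sphere concentration must exceed background concentration")
    contrast = a_sphere / a_bkg

    rois = bkg_rois_xy if bkg_rois_xy is not None else default_background_rois(spec, bkg_roi_diameter_mm)
    sphere_z = float(np.mean([s.center_mm[2] for s in spec.spheres]))
    c_bkg = _background_mean(volume, rois, bkg_roi_diameter_mm, sphere_z)
    if not c_bkg > 0:
        raise AnalysisError("measured background concentration is not positive")
    bias = c_bkg / (a_bkg * 1000.0)

    a_sphere_bq = a_sphere * 1000.0
    rows = []
    flags: list[str] = []
    for s in sorted(spec.spheres, key=lambda s: s.inner_diameter_mm):
        d = s.inner_diameter_mm
        row = {
            "diameter_mm": d,
            "crc_max": np.nan,
            "crc_mean": np.nan,
            "crc_peak": np.nan,
            "rc_max": np.nan,
            "rc_mean": np.nan,
            "rc_peak": np.nan,
            "informational": not any(abs(d - cd) < 0.1 for cd in criteria_diameters),
        }
        try:
            center = locate_sphere_centroid(volume, s.center_mm, d, background_bq_ml=c_bkg)
            m = sphere_voi_stats(volume, center, d, peak_volume_ml, supersampling)
        except (DetectionError, AnalysisError) as exc:
            flags.append(f"sphere {d:g} mm: {exc}")
            rows.append(row)
            continue
        for metric, c_val in (("max", m.c_max), ("mean", m.c_mean), ("peak", m.c_peak)):
            row[f"crc_{metric}"] = crc(c_val, c_bkg, a_sphere_bq, a_bkg * 1000.0)
            row[f"rc_{metric}"] = rc(c_val, a_sphere_bq)
        rows.append(row)

    return RecoveryCurve(
        contrast=contrast,
        calibration_bias=bias,
        rows=pd.DataFrame(rows),
        c_bkg_bq_ml=c_bkg,
        a_bkg_kbq_ml=a_bkg,
        a_sphere_kbq_ml=a_sphere,
        acquisition_start=t,
        radionuclide=volume.radionuclide,
        supersampling=supersampling,
        flags=flags,
    )
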