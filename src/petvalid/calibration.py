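"""Calibration-bias analysis of a uniform-region phantom volume.

Scanner calibration accuracy is reported as the calibration bias

    bias = C_bkg / A_bkg,

the image-derived background concentration divided by the assay-derived
ground-truth concentration decay-corrected to the acquisition start.
C_bkg is sampled with slice-wise circular ROIs whose diameter is the
phantom diameter minus a 2-cm margin (to avoid edge partial-volume
effects); the per-slice and global (slice-averaged) biases are both
reported, along with the axial uniformity (the worst per-slice departure
from the global bias).

Slices whose centers lie within 10 mm of either physical phantom end are
excluded by default: the radial margin handles the wall, but axial
partial-volume at the end caps needs its own guard band.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .fills import FillRecord, concentration_at
from .imaging import ImageVolume
from .phantoms import PhantomSpec

__all__ = [
    "CalibrationResult",
    "slice_roi_means",
    "calibration_bias",
    "analyze_calibration",
    "multi_position_summary",
]


@dataclass
class CalibrationResult:
    """Per-slice and global calibration bias for one phantom acquisition."""

    per_slice: pd.DataFrame  # columns: slice_index, mean_bq_ml, bias
    global_bias: float
    axial_uniformity: float
    roi_diameter_mm: float
    slices_used: tuple[int, int]  # inclusive index range
    a_bkg_kbq_ml: float
    acquisition_start: datetime
    radionuclide: str

    def to_json_dict(self) -> dict:
        return {
            "global_bias": self.global_bias,
            "axial_uniformity": self.axial_uniformity,
            "roi_diameter_mm": self.roi_diameter_mm,
            "slices_used": list(self.slices_used),
            "a_bkg_kbq_ml": self.a_bkg_kbq_ml,
            "acquisition_start": self.acquisition_start.isoformat(),
            "radionuclide": self.radionuclide,
            "per_slice": self.per_slice.to_dict(orient="records"),
        }


def slice_roi_means(
    volume: ImageVolume,
    axis_center_mm: tuple[float, float] = (0.0, 0.0),
    phantom_diameter_mm: float = 200.0,
    margin_mm: float = 20.0,
) -> pd.DataFrame:
    """Mean voxel value inside a circular ROI, per transaxial slice.

    The ROI diameter is ``phantom_diameter − margin`` (default margin 2 cm,
    i.e. a 180-mm ROI on the 20-cm phantom); membership is by voxel-center
    inclusion.  Raises if the ROI does not fit inside the grid.
    """
    roi_d = phantom_diameter_mm - margin_mm
    if not roi_d > 0:
        raise AnalysisError(f"ROI diameter {roi_d:g} mm must be positive")
    r = roi_d / 2.0
    cx, cy = axis_center_mm
    lo, hi = volume.world_extent()
    if cx - r < lo[0] or cx + r > hi[0] or cy - r < lo[1] or cy + r > hi[1]:
        raise AnalysisError("circular ROI extends outside the image grid")
    xs = volume.axis_coords(0)
    ys = volume.axis_coords(1)
    mask = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= r**2
    if not mask.any():
        raise AnalysisError("ROI contains no voxel centers; grid too coarse")
    means = volume.voxels[mask, :].mean(axis=0)
    return pd.DataFrame(
        {"slice_index": np.arange(volume.shape[2]), "mean_bq_ml": means}
    )


def calibration_bias(c_bkg_kbq_ml: float, a_bkg_kbq_ml: float) -> float:
    """Image-derived over true background concentration (dimensionless)."""
    if not a_bkg_kbq_ml > 0:
        raise AnalysisError(f"true background concentration must be positive, got {a_bkg_kbq_ml}")
    return c_bkg_kbq_ml / a_bkg_kbq_ml


def analyze_calibration(
    volume: ImageVolume,
    fill: FillRecord,
    spec: PhantomSpec,
    axis_center_mm: tuple[float, float] = (0.0, 0.0),
    margin_mm: float = 20.0,
    end_exclusion_mm: float = 10.0,
) -> CalibrationResult:
    """Full calibration analysis: decay-correct the fill, ROI every slice, average.

    The phantom is assumed centered axially at z = 0 (world coordinates).
    ``A_bkg`` is referenced to the volume's acquisition start ("concentration
    at scan time").
    """
    if fill.radionuclide.name != volume.radionuclide:
        raise AnalysisError(
            f"fill radionuclide {fill.radionuclide.name} does not match volume "
            f"radionuclide {volume.radionuclide}"
        )
    if spec.kind != "uniform_cylinder":
        raise AnalysisError(
            "calibration analysis requires a uniform-cylinder phantom (or declared uniform subregion)"
        )
    a_bkg = concentration_at(fill, volume.acquisition_start)

    table = slice_roi_means(volume, axis_center_mm, spec.cylinder_diameter_mm, margin_mm)
    zc = volume.axis_coords(2)
    half = spec.axial_length_mm / 2.0
    keep = (zc >= -half + end_exclusion_mm) & (zc <= half - end_exclusion_mm)
    if not keep.any():
        raise AnalysisError("no slices remain after end exclusion")
    table = table[keep].reset_index(drop=True)
    table["bias"] = table["mean_bq_ml"] / (a_bkg * 1000.0)
    global_bias = float(table["bias"].mean())
    uniformity = float(np.max(np.abs(table["bias"] - global_bias)) / global_bias)
    return CalibrationResult(
        per_slice=table,
        global_bias=global_bias,
        axial_uniformity=uniformity,
        roi_diameter_mm=spec.cylinder_diameter_mm - margin_mm,
        slices_used=(int(table["slice_index"].iloc[0]), int(table["slice_index"].iloc[-1])),
        a_bkg_kbq_ml=a_bkg,
        acquisition_start=volume.acquisition_start,
        radionuclide=volume.radionuclide,
    )


def multi_position_summary(results: list[tuple[str, CalibrationResult]]) -> pd.DataFrame:
    """Summarize global bias across axial positions (long-axial-FOV check).

    ``results`` is a list of (position label, result) pairs, e.g. the
    phantom scanned at 1/4, 1/2 and 3/4 of the axial FOV.  The returned
    frame carries one row per position plus the maximum pairwise relative
    bias difference (relative to the smaller of each pair) in
    ``attrs["max_pairwise_rel_diff"]``.
    """
    if len(results) < 2:
        raise AnalysisError("multi-position summary needs at least 2 positions")
    df = pd.DataFrame(
        {
            "position": [label for label, _ in results],
            "global_bias": [r.global_bias for _, r in results],
        }
    )
    biases = df["global_bias"].to_numpy()
    diffs = [
        abs(biases[i] - biases[j]) / min(biases[i], biases[j])
        for i in range(len(biases))
        for j in range(i + 1, len(biases))
    ]
    df.attrs["max_pairwise_rel_diff"] = float(max(diffs))
    return df
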