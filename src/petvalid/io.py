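"""Volume readers/writers and the end-to-end validation runner.

The canonical interchange format is NIfTI (.nii.gz) plus a JSON sidecar
carrying the metadata NIfTI cannot: units (must be Bq/mL), radionuclide and
acquisition start.  A DICOM PET series can be *read* through an adapter
(rescale slope/intercept applied, BQML units asserted) but is never
written — version-controlled fixtures stay bit-exact as NIfTI + JSON.

Missing units or acquisition-time metadata is a hard error; guessing either
would silently corrupt every decay correction downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .calibration import analyze_calibration
from .criteria import (
    CalibrationCriteria,
    CrcCriteria,
    decision_to_json,
    decision_to_markdown,
    evaluate_calibration,
    evaluate_crc,
    input_digest,
    load_criteria,
)
from .errors import MetadataError, PetValidError
from .fills import concentration_at, fill_qc, read_fills_json
from .imaging import ImageVolume
from .phantoms import load_phantom_json
from .recovery import analyze_recovery

logger = logging.getLogger("petvalid")

__all__ = ["read_volume", "write_volume", "read_dicom_series", "RunConfig", "run_validation"]


def write_volume(
    volume: ImageVolume,
    path: str | Path,
    sidecar_path: str | Path | None = None,
    extra: dict | None = None,
) -> None:
    """Write a volume as NIfTI with a JSON metadata sidecar."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float64), volume.affine)
    nib.save(img, str(path))
    sidecar = {
        "units": volume.units,
        "radionuclide": volume.radionuclide,
        "acquisition_start": volume.acquisition_start.isoformat(),
    }
    sidecar.update(extra or {})
    if sidecar_path is None:
        sidecar_path = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_volume(path: str | Path, sidecar_path: str | Path | None = None) -> ImageVolume:
    """Read a NIfTI volume + JSON sidecar into an :class:`ImageVolume`."""
    if sidecar_path is None:
        sidecar_path = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("units", "radionuclide", "acquisition_start"):
        if key not in meta:
            raise MetadataError(f"sidecar lacks required key {key!r}")
    if meta["units"] != "Bq/mL":
        raise MetadataError(f"unsupported units {meta['units']!r}; volumes must be Bq/mL")
    img = nib.load(str(path))
    aff = img.affine
    offdiag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(offdiag, 0.0, atol=1e-6):
        raise MetadataError("only axis-aligned (diagonal-affine) volumes are supported")
    spacing = tuple(float(x) for x in np.diag(aff[:3, :3]))
    if any(s <= 0 for s in spacing):
        raise MetadataError(f"nonpositive voxel spacing {spacing}")
    return ImageVolume(
        voxels=np.asarray(img.dataobj, dtype=np.float64),
        spacing_mm=spacing,  # type: ignore[arg-type]
        origin_mm=tuple(float(x) for x in aff[:3, 3]),  # type: ignore[arg-type]
        acquisition_start=datetime.fromisoformat(meta["acquisition_start"]),
        radionuclide=meta["radionuclide"],
    )


def read_dicom_series(directory: str | Path) -> ImageVolume:
    """Read a DICOM PET series directory (adapter; BQML units required).

    Slices are sorted by z position; rescale slope/intercept are applied.
    Inconsistent spacing or orientation across the series is an error.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm")) or sorted(Path(directory).iterdir())
    datasets = []
    for f in files:
        if f.is_file():
            try:
                datasets.append(pydicom.dcmread(str(f)))
            except Exception:
                continue
    if not datasets:
        raise MetadataError(f"no readable DICOM files in {directory}")

    units = getattr(datasets[0], "Units", None)
    if units != "BQML":
        raise MetadataError(f"DICOM Units must be BQML, got {units!r}")

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    px = [tuple(float(v) for v in ds.PixelSpacing) for ds in datasets]
    if len(set(px)) != 1:
        raise MetadataError("inconsistent PixelSpacing across the DICOM series")
    zs = [float(ds.ImagePositionPatient[2]) for ds in datasets]
    dz = np.diff(zs)
    if len(dz) and not np.allclose(dz, dz[0], atol=1e-3):
        raise MetadataError("inconsistent slice spacing across the DICOM series")

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # DICOM pixel_array is (row=y, col=x); reorder to (x, y, z)
    vox = np.stack(slices, axis=-1).transpose(1, 0, 2)

    ds0 = datasets[0]
    acq_date = getattr(ds0, "AcquisitionDate", None) or getattr(ds0, "SeriesDate", None)
    acq_time = getattr(ds0, "AcquisitionTime", None) or getattr(ds0, "SeriesTime", None)
    if not acq_date or not acq_time:
        raise MetadataError("DICOM series lacks acquisition date/time")
    t = datetime.strptime(acq_date + acq_time.split(".")[0], "%Y%m%d%H%M%S")
    nuclide = "F-18"
    try:
        nuclide = str(
            ds0.RadiopharmaceuticalInformationSequence[0]
            .RadionuclideCodeSequence[0]
            .CodeMeaning
        )
    except Exception:
        pass
    row_dy, col_dx = px[0]
    ipp = [float(v) for v in ds0.ImagePositionPatient]
    return ImageVolume(
        voxels=vox,
        spacing_mm=(col_dx, row_dy, float(dz[0]) if len(dz) else 1.0),
        origin_mm=(ipp[0], ipp[1], zs[0]),
        acquisition_start=t,
        radionuclide=nuclide,
    )


# ---------------------------------------------------------------------------
# end-to-end runner

@dataclass
class RunConfig:
    """Inputs and options for one end-to-end validation run."""

    mode: str  # "calibration" | "recovery"
    volume_path: Path
    fills_path: Path
    phantom_path: Path
    out_dir: Path
    sidecar_path: Path | None = None
    criteria_path: Path | None = None
    tier: int = 1
    nuclide: str | None = None
    margin_mm: float = 20.0
    supersampling: int = 1
    peak_volume_ml: float = 1.0
    seed: int = 0


def run_validation(config: RunConfig) -> int:
    """Run fill QC → analysis → criteria → report; exit code 0 pass / 1 fail / 2 error."""
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        log_lines = [f"petvalid {__version__} mode={config.mode}"]
        for label, p in (
            ("volume", config.volume_path),
            ("fills", config.fills_path),
            ("phantom", config.phantom_path),
        ):
            if not Path(p).exists():
                raise MetadataError(f"missing {label} file: {p}")
            log_lines.append(f"input {label} sha256={input_digest(p)} path={p}")

        volume = read_volume(config.volume_path, config.sidecar_path)
        fills = {f.compartment_kind: f for f in read_fills_json(config.fills_path)}
        spec = load_phantom_json(config.phantom_path)
        criteria_cfg = load_criteria(config.criteria_path)
        nuclide = config.nuclide or volume.radionuclide

        if config.mode == "calibration":
            fill = fills["background"]
            plan = {
                "scan_kind": "calibration",
                "bkg_conc_kbq_ml": concentration_at(fill, volume.acquisition_start),
                "total_activity_in_fov_mbq": float(
                    volume.voxels.sum() * volume.voxel_volume_ml / 1e6
                ),
            }
            qc = fill_qc(plan)
            result = analyze_calibration(volume, fill, spec, margin_mm=config.margin_mm)
            result.per_slice.to_csv(out / "calibration_slices.csv", index=False)
            decision = evaluate_calibration(
                result,
                nuclide,
                config.tier,
                criteria=CalibrationCriteria.from_config(config.tier, criteria_cfg),
            )
        elif config.mode == "recovery":
            a_bkg = concentration_at(fills["background"], volume.acquisition_start)
            a_sph = concentration_at(fills["sphere_stock"], volume.acquisition_start)
            plan = {
                "scan_kind": "rc",
                "bkg_conc_kbq_ml": a_bkg,
                "contrast": a_sph / a_bkg,
                "total_activity_in_fov_mbq": float(
                    volume.voxels.sum() * volume.voxel_volume_ml / 1e6
                ),
            }
            qc = fill_qc(plan)
            curve = analyze_recovery(
                volume,
                fills,
                spec,
                supersampling=config.supersampling,
                peak_volume_ml=config.peak_volume_ml,
            )
            curve.rows.to_csv(out / "recovery_curve.csv", index=False)
            (out / "recovery_curve.json").write_text(
                json.dumps(curve.to_json_dict(), indent=2, sort_keys=True, default=str)
            )
            decision = evaluate_crc(curve, criteria=CrcCriteria.from_config(criteria_cfg))
        else:
            raise MetadataError(f"unknown mode {config.mode!r}")

        for flag in qc:
            log_lines.append(f"fill-qc [{flag.severity}] {flag.code}: {flag.message}")
        (out / "decision.json").write_text(decision_to_json(decision))
        (out / "report.md").write_text(decision_to_markdown(decision))
        log_lines.append(f"decision passed={decision.passed}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        return 0 if decision.passed else 1
    except PetValidError as exc:
        if out.exists():
            (out / "error.log").write_text(f"{type(exc).__name__}: {exc}\n")
        logger.error("validation failed: %s", exc)
        return 2
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        logger.error("validation errored: %s", exc)
        return 2
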