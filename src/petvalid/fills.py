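"""Phantom fill accounting: assays, net activities, concentrations and fill QC.

A phantom fill is documented by a pre-injection and a post-injection
(residual) syringe assay on a radionuclide calibrator, plus the aqueous
volume of the compartment being filled.  Net activity decay-corrected to
scan time divided by compartment volume gives the ground-truth activity
concentration (kBq/mL) against which the scanner is judged.

Recommended operating points encoded here as defaults:

* calibration (uniform-phantom) background: 3–7 kBq/mL;
* recovery (sphere-phantom) background: 2–6 kBq/mL at scan time;
* sphere-to-background contrast: 8:1 (16 kBq/mL spheres over a 2 kBq/mL
  background);
* keep total activity in the field of view under ~40 MBq to avoid dead-time
  and pulse-pileup concentration bias.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable

from .errors import FillRecordError
from .nuclides import Radionuclide, decay_correct, get_nuclide

__all__ = [
    "ActivityAssay",
    "FillRecord",
    "QcFlag",
    "QcLimits",
    "RECOMMENDED_CONTRAST",
    "WATER_DENSITY_20C",
    "net_activity_at",
    "volume_from_weight",
    "concentration_at",
    "achieved_contrast",
    "plan_rc_fill",
    "fill_qc",
    "clock_sync_flags",
    "fill_to_dict",
    "fill_from_dict",
    "write_fills_json",
    "read_fills_json",
    "read_assays_csv",
]

#: Density of water at 20 °C in g/mL, the default for volume-by-weight.
WATER_DENSITY_20C = 0.9982

#: Recommended sphere-to-background contrast ratio for recovery phantoms.
RECOMMENDED_CONTRAST = 8.0


@dataclass(frozen=True)
class ActivityAssay:
    """A single radionuclide-calibrator activity measurement.

    ``clock_offset_s`` is the signed offset of the assay device clock
    relative to the scanner clock (device − scanner), used only for QC:
    clocks should agree to better than one minute.
    """

    activity_mbq: float
    assay_time: datetime
    device_id: str = ""
    clock_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.activity_mbq < 0:
            raise FillRecordError(f"assay activity must be ≥ 0, got {self.activity_mbq}")


@dataclass(frozen=True)
class FillRecord:
    """Accounting record for one phantom compartment fill.

    ``compartment_kind`` is ``"background"`` (phantom body) or
    ``"sphere_stock"`` (the dilution-flask solution used to fill spheres).
    """

    radionuclide: Radionuclide
    pre_assay: ActivityAssay
    post_assay: ActivityAssay
    fill_time: datetime
    compartment_volume_ml: float
    compartment_kind: str = "background"

    def __post_init__(self) -> None:
        if not self.compartment_volume_ml > 0:
            raise FillRecordError(
                f"compartment volume must be positive, got {self.compartment_volume_ml}"
            )
        if self.compartment_kind not in ("background", "sphere_stock"):
            raise FillRecordError(f"unknown compartment kind {self.compartment_kind!r}")
        # invariant: decay-corrected pre ≥ decay-corrected post at fill time
        pre = decay_correct(
            self.pre_assay.activity_mbq, self.pre_assay.assay_time, self.fill_time, self.radionuclide
        )
        post = decay_correct(
            self.post_assay.activity_mbq, self.post_assay.assay_time, self.fill_time, self.radionuclide
        )
        if post > pre:
            raise FillRecordError(
                f"residual assay ({post:.6g} MBq) exceeds pre-fill assay ({pre:.6g} MBq) "
                "when decay-corrected to fill time"
            )


def net_activity_at(fill: FillRecord, reference_time: datetime) -> float:
    """Net activity (MBq) injected into the compartment, at ``reference_time``.

    Pre and residual assays are decay-corrected independently to the
    reference time and differenced; the result is therefore invariant to the
    choice of any intermediate common correction time.
    """
    pre = decay_correct(
        fill.pre_assay.activity_mbq, fill.pre_assay.assay_time, reference_time, fill.radionuclide
    )
    post = decay_correct(
        fill.post_assay.activity_mbq, fill.post_assay.assay_time, reference_time, fill.radionuclide
    )
    net = pre - post
    if net < 0:
        raise FillRecordError(f"negative net activity ({net:.6g} MBq)")
    return net


def volume_from_weight(gross_mass_g: float, empty_mass_g: float, water_density_g_ml: float = WATER_DENSITY_20C) -> float:
    """Compartment volume (mL) from gross and empty (tare) masses on a scale."""
    if not water_density_g_ml > 0:
        raise FillRecordError(f"density must be positive, got {water_density_g_ml}")
    net = gross_mass_g - empty_mass_g
    if not net > 0:
        raise FillRecordError(
            f"gross mass ({gross_mass_g} g) must exceed empty mass ({empty_mass_g} g)"
        )
    return net / water_density_g_ml


def concentration_at(fill: FillRecord, reference_time: datetime) -> float:
    """Ground-truth activity concentration (kBq/mL) at ``reference_time``."""
    return net_activity_at(fill, reference_time) * 1000.0 / fill.compartment_volume_ml


def achieved_contrast(sphere_conc_kbq_ml: float, bkg_conc_kbq_ml: float) -> float:
    """Sphere-to-background concentration ratio."""
    if not bkg_conc_kbq_ml > 0:
        raise FillRecordError(f"background concentration must be positive, got {bkg_conc_kbq_ml}")
    return sphere_conc_kbq_ml / bkg_conc_kbq_ml


def plan_rc_fill(bkg_conc_kbq_ml: float, contrast: float = RECOMMENDED_CONTRAST) -> dict:
    """Plan a recovery-phantom fill: sphere concentration for a target contrast.

    Returns a dict with the background concentration, contrast and the
    sphere (stock) concentration required at imaging time; e.g. a 2 kBq/mL
    background at the recommended 8:1 contrast needs 16 kBq/mL spheres.
    """
    if not bkg_conc_kbq_ml > 0:
        raise FillRecordError(f"background concentration must be positive, got {bkg_conc_kbq_ml}")
    if not contrast > 1:
        raise FillRecordError(f"contrast must exceed 1, got {contrast}")
    return {
        "bkg_conc_kbq_ml": bkg_conc_kbq_ml,
        "contrast": contrast,
        "sphere_conc_kbq_ml": bkg_conc_kbq_ml * contrast,
    }


@dataclass(frozen=True)
class QcFlag:
    """One fill-QC finding; ``severity`` is ``"warning"`` or ``"fail"``."""

    code: str
    message: str
    severity: str = "warning"


@dataclass(frozen=True)
class QcLimits:
    """Configurable fill-QC limits, defaulting to the recommended values."""

    calibration_bkg_kbq_ml: tuple[float, float] = (3.0, 7.0)
    rc_bkg_kbq_ml: tuple[float, float] = (2.0, 6.0)
    fov_activity_warn_mbq: float = 40.0
    contrast_target: float = RECOMMENDED_CONTRAST
    contrast_rel_tol: float = 0.10
    clock_offset_max_s: float = 60.0


def fill_qc(fill_plan: dict, limits: QcLimits | None = None) -> list[QcFlag]:
    """Check a fill plan against the recommended operating ranges.

    ``fill_plan`` keys: ``scan_kind`` (``"calibration"`` or ``"rc"``),
    ``bkg_conc_kbq_ml``, ``contrast`` (rc only), ``total_activity_in_fov_mbq``.
    QC never raises; it returns a (possibly empty) list of flags.
    """
    limits = limits or QcLimits()
    flags: list[QcFlag] = []
    kind = fill_plan.get("scan_kind", "calibration")
    bkg = fill_plan.get("bkg_conc_kbq_ml")

    if bkg is not None:
        if kind == "calibration":
            lo, hi = limits.calibration_bkg_kbq_ml
            if not lo <= bkg <= hi:
                flags.append(
                    QcFlag(
                        "calibration_bkg_range",
                        f"calibration background {bkg:g} kBq/mL outside recommended "
                        f"{lo:g}–{hi:g} kBq/mL",
                    )
                )
        else:
            lo, hi = limits.rc_bkg_kbq_ml
            if bkg > hi:
                flags.append(
                    QcFlag(
                        "rc_bkg_exceeds_limit",
                        f"background {bkg:g} kBq/mL exceeds the {hi:g} kBq/mL limit "
                        "(dead-time correction may bias concentrations)",
                        severity="fail",
                    )
                )
            elif bkg < lo:
                flags.append(
                    QcFlag(
                        "rc_bkg_low",
                        f"background {bkg:g} kBq/mL below the recommended minimum {lo:g} kBq/mL",
                    )
                )

    contrast = fill_plan.get("contrast")
    if contrast is not None and kind != "calibration":
        rel = abs(contrast - limits.contrast_target) / limits.contrast_target
        if rel > limits.contrast_rel_tol:
            flags.append(
                QcFlag(
                    "contrast_deviation",
                    f"achieved contrast {contrast:g}:1 deviates from the "
                    f"{limits.contrast_target:g}:1 target by {rel:.0%}",
                )
            )

    fov = fill_plan.get("total_activity_in_fov_mbq")
    if fov is not None and fov > limits.fov_activity_warn_mbq:
        flags.append(
            QcFlag(
                "fov_activity_dead_time",
                f"{fov:g} MBq in the field of view exceeds ~{limits.fov_activity_warn_mbq:g} MBq; "
                "pulse pileup / dead time may bias the concentration measurement",
            )
        )
    return flags


def clock_sync_flags(fill: FillRecord, limits: QcLimits | None = None) -> list[QcFlag]:
    """Flag assay devices whose clock offset to the scanner is ≥ the limit (1 min default)."""
    limits = limits or QcLimits()
    flags = []
    for label, assay in (("pre_assay", fill.pre_assay), ("post_assay", fill.post_assay)):
        if abs(assay.clock_offset_s) >= limits.clock_offset_max_s:
            flags.append(
                QcFlag(
                    "clock_offset",
                    f"{label} device {assay.device_id!r} clock offset "
                    f"{assay.clock_offset_s:g} s ≥ {limits.clock_offset_max_s:g} s",
                )
            )
    return flags


# ---------------------------------------------------------------------------
# serialization (JSON with ISO-8601 times, MBq, mL)

def _assay_to_dict(a: ActivityAssay) -> dict:
    return {
        "activity_mbq": a.activity_mbq,
        "assay_time": a.assay_time.isoformat(),
        "device_id": a.device_id,
        "clock_offset_s": a.clock_offset_s,
    }


def _assay_from_dict(d: dict) -> ActivityAssay:
    return ActivityAssay(
        activity_mbq=float(d["activity_mbq"]),
        assay_time=datetime.fromisoformat(d["assay_time"]),
        device_id=d.get("device_id", ""),
        clock_offset_s=float(d.get("clock_offset_s", 0.0)),
    )


def fill_to_dict(fill: FillRecord) -> dict:
    return {
        "radionuclide": fill.radionuclide.name,
        "pre_assay": _assay_to_dict(fill.pre_assay),
        "post_assay": _assay_to_dict(fill.post_assay),
        "fill_time": fill.fill_time.isoformat(),
        "compartment_volume_ml": fill.compartment_volume_ml,
        "compartment_kind": fill.compartment_kind,
    }


def fill_from_dict(d: dict) -> FillRecord:
    return FillRecord(
        radionuclide=get_nuclide(d["radionuclide"]),
        pre_assay=_assay_from_dict(d["pre_assay"]),
        post_assay=_assay_from_dict(d["post_assay"]),
        fill_time=datetime.fromisoformat(d["fill_time"]),
        compartment_volume_ml=float(d["compartment_volume_ml"]),
        compartment_kind=d.get("compartment_kind", "background"),
    )


def write_fills_json(fills: Iterable[FillRecord], path: str | Path) -> None:
    Path(path).write_text(json.dumps([fill_to_dict(f) for f in fills], indent=2, sort_keys=True))


def read_fills_json(path: str | Path) -> list[FillRecord]:
    return [fill_from_dict(d) for d in json.loads(Path(path).read_text())]


def read_assays_csv(path: str | Path) -> list[ActivityAssay]:
    """Import an assay table (columns: activity_mbq, assay_time, device_id, clock_offset_s)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ActivityAssay(
                    activity_mbq=float(row["activity_mbq"]),
                    assay_time=datetime.fromisoformat(row["assay_time"]),
                    device_id=row.get("device_id", "") or "",
                    clock_offset_s=float(row.get("clock_offset_s", 0) or 0),
                )
            )
    return out
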