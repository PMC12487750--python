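"""Acceptance criteria engine: tiered calibration tolerances, harmonized CRC
limits, validity windows and revalidation triggers.

Calibration tolerances are tiered by trial needs: tier 1 (quantitative end
points) requires |bias − 1| ≤ 5% for F-18 and Ga-68 (validated quarterly)
and ≤ 10% for other radionuclides (annually); tier 2 (visual-only end
points) allows 10% for all radionuclides.  Bounds are inclusive at the
printed value; a strict mode (exclusive comparison) is available because
the two readings coexist in practice.

Recovery harmonization is judged on the maximum-voxel CRC per sphere at
8:1 contrast against per-diameter min/max limits (EARL 2–concordant).  The
limits live in a JSON criteria table shipped as package data, so extending
the curve to smaller spheres is a data change, not a code change.

Every decision carries a validity window and a required human sign-off
field: trained human review of the phantom images for artifacts is part of
the paradigm and is deliberately not automated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from datetime import date
from importlib import resources
from pathlib import Path

import pandas as pd

from .calibration import CalibrationResult
from .errors import CriteriaError
from .nuclides import Radionuclide, get_nuclide
from .recovery import RecoveryCurve

__all__ = [
    "CalibrationCriteria",
    "CrcCriteria",
    "Finding",
    "ValidationDecision",
    "load_criteria",
    "evaluate_calibration",
    "evaluate_crc",
    "validity_window",
    "apply_events",
    "decision_to_json",
    "decision_to_markdown",
]

QUARTERLY_NUCLIDES = ("F-18", "Ga-68")


def load_criteria(path: str | Path | None = None) -> dict:
    """Load a criteria configuration; the packaged defaults when no path given."""
    if path is None:
        ref = resources.files("petvalid").joinpath("data/default_criteria.json")
        return json.loads(ref.read_text())
    return json.loads(Path(path).read_text())


@dataclass(frozen=True)
class CalibrationCriteria:
    """Tiered calibration-bias tolerances and validation frequencies."""

    tier: int
    tolerance_by_nuclide: dict
    frequency_by_nuclide: dict
    strict: bool = False

    def __post_init__(self) -> None:
        if self.tier not in (1, 2):
            raise CriteriaError(f"tier must be 1 or 2, got {self.tier}")
        for tol in self.tolerance_by_nuclide.values():
            if not 0 < tol < 1:
                raise CriteriaError(f"tolerances must be in (0, 1), got {tol}")

    @classmethod
    def from_config(cls, tier: int, config: dict | None = None, strict: bool = False):
        config = config or load_criteria()
        key = f"tier{tier}"
        try:
            tols = dict(config["calibration_tolerance"][key])
        except KeyError:
            raise CriteriaError(f"criteria config lacks calibration tolerances for tier {tier}") from None
        freq = dict(config["frequency"]["calibration"])
        return cls(tier=tier, tolerance_by_nuclide=tols, frequency_by_nuclide=freq, strict=strict)

    def tolerance_for(self, nuclide: Radionuclide) -> float:
        return self.tolerance_by_nuclide.get(nuclide.name, self.tolerance_by_nuclide["default"])


@dataclass(frozen=True)
class CrcCriteria:
    """Per-diameter maximum-voxel CRC acceptance limits at a fixed contrast."""

    contrast: float
    metric: str
    limits: dict  # diameter_mm -> (min, max)

    def __post_init__(self) -> None:
        for d, (lo, hi) in self.limits.items():
            if not lo < hi:
                raise CriteriaError(f"CRC limits for {d} mm must satisfy min < max")

    @classmethod
    def from_config(cls, config: dict | None = None):
        config = config or load_criteria()
        limits = {
            float(row["diameter_mm"]): (float(row["min"]), float(row["max"]))
            for row in config["crc_limits"]
        }
        return cls(contrast=float(config.get("contrast", 8)), metric=config.get("metric", "max"), limits=limits)


@dataclass(frozen=True)
class Finding:
    """One judged item inside a decision."""

    item: str
    value: float | None
    bound: str
    verdict: str  # "pass" | "fail" | "informational"


@dataclass(frozen=True)
class ValidationDecision:
    """Structured pass/fail record with provenance and a validity window.

    ``human_review`` stays ``None`` until a qualified reviewer signs off on
    the images; automated criteria never populate it.
    """

    subject: str  # "calibration" | "recovery" | "phantom"
    passed: bool
    findings: tuple[Finding, ...]
    valid_from: date
    valid_until: date
    provenance: dict = field(default_factory=dict)
    human_review: str | None = None

    def __post_init__(self) -> None:
        if not self.valid_until > self.valid_from:
            raise CriteriaError("valid_until must be after valid_from")
        failing = any(f.verdict == "fail" for f in self.findings)
        if self.passed == failing:
            raise CriteriaError("passed flag inconsistent with findings")


def _add_months(d: date, months: int) -> date:
    """Calendar-month arithmetic with day clamped to the target month length."""
    import calendar

    y, m = divmod(d.month - 1 + months, 12)
    y += d.year
    m += 1
    day = min(d.day, calendar.monthrange(y, m)[1])
    return date(y, m, day)


def validity_window(
    scan_date: date,
    nuclide: Radionuclide | str,
    purpose: str,
    quarter_months: int = 3,
) -> tuple[date, date]:
    """Validity window starting on the validation-scan date.

    Calibration with F-18/Ga-68: quarterly (+3 calendar months by default;
    configurable because "quarterly" is not pinned to 90 days anywhere).
    All other calibrations and every recovery validation: +1 year.
    """
    nuc = get_nuclide(nuclide) if isinstance(nuclide, str) else nuclide
    if purpose not in ("calibration", "recovery"):
        raise CriteriaError(f"purpose must be calibration or recovery, got {purpose!r}")
    if purpose == "calibration" and nuc.name in QUARTERLY_NUCLIDES:
        return scan_date, _add_months(scan_date, quarter_months)
    return scan_date, _add_months(scan_date, 12)


def evaluate_calibration(
    result: CalibrationResult,
    nuclide: Radionuclide | str,
    tier: int,
    criteria: CalibrationCriteria | None = None,
    scan_date: date | None = None,
) -> ValidationDecision:
    """Judge a calibration result: pass iff |global_bias − 1| ≤ tolerance."""
    nuc = get_nuclide(nuclide) if isinstance(nuclide, str) else nuclide
    crit = criteria or CalibrationCriteria.from_config(tier)
    tol = crit.tolerance_for(nuc)
    dev = abs(result.global_bias - 1.0)
    # 1e-12 guard so a bias exactly at the printed boundary is not rejected
    # by binary round-off (0.05 is not representable exactly)
    ok = dev < tol if crit.strict else dev <= tol + 1e-12
    findings = (
        Finding(
            item="global_calibration_bias",
            value=result.global_bias,
            bound=f"|bias − 1| {'<' if crit.strict else '≤'} {tol:g}",
            verdict="pass" if ok else "fail",
        ),
        Finding(
            item="axial_uniformity",
            value=result.axial_uniformity,
            bound="reported for inspection",
            verdict="informational",
        ),
    )
    scan_date = scan_date or result.acquisition_start.date()
    valid_from, valid_until = validity_window(scan_date, nuc, "calibration")
    return ValidationDecision(
        subject="calibration",
        passed=ok,
        findings=findings,
        valid_from=valid_from,
        valid_until=valid_until,
        provenance={
            "nuclide": nuc.name,
            "tier": tier,
            "tolerance": tol,
            "a_bkg_kbq_ml": result.a_bkg_kbq_ml,
            "roi_diameter_mm": result.roi_diameter_mm,
        },
    )


def evaluate_crc(
    curve: RecoveryCurve,
    criteria: CrcCriteria | None = None,
    scan_date: date | None = None,
) -> ValidationDecision:
    """Judge a recovery curve on maximum-voxel CRC against per-sphere limits.

    Every mandated diameter must be present in the curve; spheres the
    criteria table does not cover (e.g. a 7-mm insert) are reported as
    informational, never judged.
    """
    crit = criteria or CrcCriteria.from_config()
    col = f"crc_{crit.metric}"
    rows = curve.rows
    findings: list[Finding] = []
    for d, (lo, hi) in sorted(crit.limits.items()):
        match = rows[abs(rows["diameter_mm"] - d) < 0.1]
        if match.empty or not match[col].notna().all():
            raise CriteriaError(f"curve lacks a valid {col} value for the mandated {d:g}-mm sphere")
        val = float(match[col].iloc[0])
        ok = lo - 1e-12 <= val <= hi + 1e-12  # inclusive at the printed boundary
        findings.append(
            Finding(
                item=f"crc_{crit.metric}_{d:g}mm",
                value=val,
                bound=f"[{lo:g}, {hi:g}]",
                verdict="pass" if ok else "fail",
            )
        )
    for _, row in rows.iterrows():
        d = float(row["diameter_mm"])
        if not any(abs(d - cd) < 0.1 for cd in crit.limits):
            findings.append(
                Finding(
                    item=f"crc_{crit.metric}_{d:g}mm",
                    value=None if pd.isna(row[col]) else float(row[col]),
                    bound="not judged (outside criteria table)",
                    verdict="informational",
                )
            )
    passed = all(f.verdict != "fail" for f in findings)
    scan_date = scan_date or curve.acquisition_start.date()
    valid_from, valid_until = validity_window(scan_date, curve.radionuclide, "recovery")
    return ValidationDecision(
        subject="recovery",
        passed=passed,
        findings=tuple(findings),
        valid_from=valid_from,
        valid_until=valid_until,
        provenance={
            "contrast": curve.contrast,
            "calibration_bias": curve.calibration_bias,
            "metric": crit.metric,
            "radionuclide": curve.radionuclide,
            "flags": list(curve.flags),
        },
    )


def apply_events(
    decision: ValidationDecision,
    events: list[dict],
    triggers: tuple[str, ...] | None = None,
) -> ValidationDecision:
    """Truncate a decision's validity at the earliest revalidation trigger.

    ``events`` are ``{"date": date|ISO string, "kind": str}``.  Triggering
    kinds default to the configured list (software update, major service,
    Ge-68 phantom replacement, calibrator repair/maintenance); other kinds
    are ignored, as are events outside the validity window.
    """
    if triggers is None:
        triggers = tuple(load_criteria()["revalidation_triggers"])
    cut = decision.valid_until
    for ev in events:
        d = ev["date"]
        if isinstance(d, str):
            d = date.fromisoformat(d)
        if ev["kind"] in triggers and decision.valid_from < d < cut:
            cut = d
    if cut == decision.valid_until:
        return decision
    prov = dict(decision.provenance)
    prov["validity_truncated_by_event"] = cut.isoformat()
    return replace(decision, valid_until=cut, provenance=prov)


# ---------------------------------------------------------------------------
# rendering

def decision_to_json(decision: ValidationDecision) -> str:
    """Deterministic JSON rendering (sorted keys, no timestamps)."""
    payload = {
        "subject": decision.subject,
        "passed": decision.passed,
        "valid_from": decision.valid_from.isoformat(),
        "valid_until": decision.valid_until.isoformat(),
        "human_review": decision.human_review,
        "provenance": decision.provenance,
        "findings": [
            {"item": f.item, "value": f.value, "bound": f.bound, "verdict": f.verdict}
            for f in decision.findings
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def decision_to_markdown(decision: ValidationDecision) -> str:
    lines = [
        f"# Scanner validation decision — {decision.subject}",
        "",
        f"**Result: {'PASS' if decision.passed else 'FAIL'}**",
        f"Valid {decision.valid_from.isoformat()} → {decision.valid_until.isoformat()}",
        "",
        "| item | value | bound | verdict |",
        "|---|---|---|---|",
    ]
    for f in decision.findings:
        val = "—" if f.value is None else f"{f.value:.4f}"
        lines.append(f"| {f.item} | {val} | {f.bound} | {f.verdict} |")
    lines += [
        "",
        f"Human image review: {decision.human_review or 'PENDING (required)'}",
    ]
    return "\n".join(lines) + "\n"


def input_digest(path: str | Path) -> str:
    """SHA-256 of a file, for decision provenance."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
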