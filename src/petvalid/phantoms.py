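"""Phantom geometry descriptions and compliance checking.

Two families of phantoms are modelled:

* a uniform cylinder (the classic 20-cm calibration phantom), and
* a torso-shaped image-quality phantom with fillable hot spheres and a
  central low-density (lung-equivalent) insert, described here as an
  elliptical cylinder body so that it can be rasterized analytically.

World coordinates are right-handed millimetres with the origin at the
phantom body centroid; the scanner axis is ``z`` and transaxial slices are
``xy`` planes.  Sphere centers are stored explicitly, which supports
non-standard layouts.

Compliance rules for a recovery phantom: noncylindrical torso-like body,
volume in excess of 9 L, axial length greater than 18 cm, at least five
fillable spheres spanning 10–28 mm inner diameter with walls of about 1 mm
or less, and at least one low-density insert.  A calibration phantom must
offer a uniform region at least 150 mm in diameter and 200 mm long.
All bounds are inclusive at the printed value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ConfigurationError

__all__ = [
    "SphereInsert",
    "ColdInsert",
    "PhantomSpec",
    "Violation",
    "BUILTIN_PHANTOMS",
    "builtin_phantom",
    "check_rc_phantom_compliance",
    "check_calibration_phantom_compliance",
    "spec_to_dict",
    "spec_from_dict",
    "load_phantom_json",
    "save_phantom_json",
]

#: The standardized recovery-sphere inner diameters (mm).
NEMA_SPHERE_DIAMETERS = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)


@dataclass(frozen=True)
class SphereInsert:
    """A fillable sphere: inner diameter, world-coordinate center, wall thickness (mm)."""

    inner_diameter_mm: float
    center_mm: tuple[float, float, float]
    wall_thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        if not self.inner_diameter_mm > 0:
            raise ConfigurationError(f"sphere diameter must be positive, got {self.inner_diameter_mm}")
        if self.wall_thickness_mm < 0:
            raise ConfigurationError(f"wall thickness must be ≥ 0, got {self.wall_thickness_mm}")


@dataclass(frozen=True)
class ColdInsert:
    """A nonradioactive low-density insert, modelled as a z-aligned cylinder.

    ``z_range_mm`` limits the axial extent; ``None`` means full body length.
    """

    shape: str = "cylinder"
    density_class: str = "lung"
    diameter_mm: float = 50.0
    center_xy_mm: tuple[float, float] = (0.0, 0.0)
    z_range_mm: tuple[float, float] | None = None


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of a phantom plus compliance metadata.

    ``kind`` is ``"uniform_cylinder"`` or ``"torso_iq"``.  For the torso
    kind the transaxial cross-section is an ellipse with semi-axes
    ``body_semi_axes_mm``; for the uniform kind it is a circle of diameter
    ``cylinder_diameter_mm``.  ``body_shape`` ("cylindrical" /
    "noncylindrical") is a declared attribute, not inferred from geometry.
    """

    name: str
    kind: str
    body_volume_l: float
    axial_length_mm: float
    body_shape: str
    spheres: tuple[SphereInsert, ...] = ()
    cold_inserts: tuple[ColdInsert, ...] = ()
    cylinder_diameter_mm: float | None = None
    body_semi_axes_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform_cylinder", "torso_iq"):
            raise ConfigurationError(f"unknown phantom kind {self.kind!r}")
        if not self.body_volume_l > 0 or not self.axial_length_mm > 0:
            raise ConfigurationError("body volume and axial length must be positive")
        if self.kind == "uniform_cylinder":
            if self.spheres:
                raise ConfigurationError("a uniform cylinder phantom has no spheres")
            if self.cylinder_diameter_mm is None:
                raise ConfigurationError("uniform_cylinder requires cylinder_diameter_mm")
        if self.kind == "torso_iq":
            if not self.spheres:
                raise ConfigurationError("a torso IQ phantom requires at least one sphere")
            if self.body_semi_axes_mm is None:
                raise ConfigurationError("torso_iq requires body_semi_axes_mm")

    @property
    def sphere_diameters(self) -> tuple[float, ...]:
        return tuple(s.inner_diameter_mm for s in self.spheres)

    def background_volume_ml(self) -> float:
        """Aqueous background volume: body volume minus spheres and cold inserts."""
        import math

        v = self.body_volume_l * 1000.0
        for s in self.spheres:
            v -= math.pi / 6.0 * s.inner_diameter_mm**3 / 1000.0
        for c in self.cold_inserts:
            z0, z1 = c.z_range_mm or (-self.axial_length_mm / 2, self.axial_length_mm / 2)
            v -= math.pi * (c.diameter_mm / 2.0) ** 2 * (z1 - z0) / 1000.0
        return v


def _ring_centers(radius: float, angles_deg, z: float = 0.0):
    import math

    return [
        (radius * math.cos(math.radians(a)), radius * math.sin(math.radians(a)), z)
        for a in angles_deg
    ]


def _build_uniform20() -> PhantomSpec:
    import math

    d, length = 200.0, 200.0
    vol_l = math.pi * (d / 2) ** 2 * length / 1e6
    return PhantomSpec(
        name="uniform20",
        kind="uniform_cylinder",
        body_volume_l=vol_l,
        axial_length_mm=length,
        body_shape="cylindrical",
        cylinder_diameter_mm=d,
    )


def _build_iq_nema() -> PhantomSpec:
    # Elliptical-cylinder surrogate of the ~9.7-L torso body, 194 mm long;
    # six spheres on a 57.2-mm ring in the z=0 plane, central lung insert.
    import math

    a, length = 150.0, 194.0
    vol_l = 9.7
    b = vol_l * 1e6 / (math.pi * a * length)
    centers = _ring_centers(57.2, [0, 60, 120, 180, 240, 300])
    spheres = tuple(
        SphereInsert(d, c, 1.0) for d, c in zip((37.0, 28.0, 22.0, 17.0, 13.0, 10.0), centers)
    )
    return PhantomSpec(
        name="iq_nema",
        kind="torso_iq",
        body_volume_l=vol_l,
        axial_length_mm=length,
        body_shape="noncylindrical",
        spheres=spheres,
        cold_inserts=(ColdInsert(diameter_mm=50.0),),
        body_semi_axes_mm=(a, b),
    )


def _build_ctn_like() -> PhantomSpec:
    # Parameterized stand-in for an anthropomorphic chest phantom: NEMA
    # sphere set plus a 7-mm sphere, two lung-like cold cylinders above the
    # sphere plane.  Not a replica of any commercial phantom.
    import math

    a, length = 160.0, 190.0
    vol_l = 10.5
    b = vol_l * 1e6 / (math.pi * a * length)
    centers = _ring_centers(57.2, [0, 60, 120, 180, 240, 300])
    spheres = [
        SphereInsert(d, c, 1.0) for d, c in zip((37.0, 28.0, 22.0, 17.0, 13.0, 10.0), centers)
    ]
    spheres.append(SphereInsert(7.0, _ring_centers(57.2, [30])[0], 0.5))
    lungs = (
        ColdInsert(diameter_mm=60.0, center_xy_mm=(-65.0, 35.0), z_range_mm=(25.0, 95.0)),
        ColdInsert(diameter_mm=60.0, center_xy_mm=(65.0, 35.0), z_range_mm=(25.0, 95.0)),
    )
    return PhantomSpec(
        name="ctn_like",
        kind="torso_iq",
        body_volume_l=vol_l,
        axial_length_mm=length,
        body_shape="noncylindrical",
        spheres=tuple(spheres),
        cold_inserts=lungs,
        body_semi_axes_mm=(a, b),
    )


_BUILDERS = {"uniform20": _build_uniform20, "iq_nema": _build_iq_nema, "ctn_like": _build_ctn_like}
BUILTIN_PHANTOMS = tuple(_BUILDERS)


def builtin_phantom(name: str) -> PhantomSpec:
    """Return a built-in phantom spec: ``uniform20``, ``iq_nema`` or ``ctn_like``.

    Specs are shipped as packaged JSON data; if the data file is absent the
    equivalent programmatic builder is used.
    """
    if name not in _BUILDERS:
        raise ConfigurationError(f"unknown phantom {name!r}; builtins: {', '.join(BUILTIN_PHANTOMS)}")
    try:
        ref = resources.files("petvalid").joinpath(f"data/phantoms/{name}.json")
        return spec_from_dict(json.loads(ref.read_text()))
    except (FileNotFoundError, ModuleNotFoundError):
        return _BUILDERS[name]()


@dataclass(frozen=True)
class Violation:
    """One compliance finding; ``severity`` is ``"fail"`` or ``"info"``."""

    code: str
    message: str
    severity: str = "fail"


def check_rc_phantom_compliance(spec: PhantomSpec, wall_tol_mm: float = 1.0) -> list[Violation]:
    """Check a phantom against the recovery-measurement requirements.

    Returns an empty list for a compliant phantom.  Bounds: volume > 9 L,
    axial length > 180 mm, noncylindrical body, ≥ 5 spheres with inner
    diameters within 10–28 mm, sphere walls ≤ ``wall_tol_mm``, and at least
    one low-density insert.
    """
    v: list[Violation] = []
    if not spec.body_volume_l > 9.0:
        v.append(Violation("volume", f"body volume {spec.body_volume_l:g} L is not in excess of 9 L"))
    if not spec.axial_length_mm > 180.0:
        v.append(
            Violation("axial_length", f"axial length {spec.axial_length_mm:g} mm is not greater than 180 mm")
        )
    if spec.body_shape != "noncylindrical":
        v.append(Violation("body_shape", "body should be noncylindrical (ideally torso shaped)"))
    mandated = [s for s in spec.spheres if 10.0 <= s.inner_diameter_mm <= 28.0]
    if len(mandated) < 5:
        v.append(
            Violation(
                "sphere_count",
                f"only {len(mandated)} spheres span 10–28 mm inner diameter; at least 5 required",
            )
        )
    for s in spec.spheres:
        if s.wall_thickness_mm > wall_tol_mm:
            v.append(
                Violation(
                    "sphere_wall",
                    f"{s.inner_diameter_mm:g}-mm sphere wall {s.wall_thickness_mm:g} mm exceeds "
                    f"{wall_tol_mm:g} mm",
                )
            )
    if not spec.cold_inserts:
        v.append(Violation("cold_insert", "no low-density insert to challenge attenuation/scatter"))
    return v


def check_calibration_phantom_compliance(spec: PhantomSpec) -> list[Violation]:
    """Check a phantom against the calibration-measurement requirements.

    Uniform cylinders need diameter ≥ 150 mm and length ≥ 200 mm (inclusive).
    Non-uniform phantoms are accepted with an informational flag: the user
    must ensure sufficient uniform regions are sampled.
    """
    v: list[Violation] = []
    if spec.kind == "uniform_cylinder":
        assert spec.cylinder_diameter_mm is not None
        if spec.cylinder_diameter_mm < 150.0:
            v.append(
                Violation(
                    "diameter",
                    f"cylinder diameter {spec.cylinder_diameter_mm:g} mm below the 150-mm minimum",
                )
            )
        if spec.axial_length_mm < 200.0:
            v.append(
                Violation(
                    "length", f"cylinder length {spec.axial_length_mm:g} mm below the 200-mm minimum"
                )
            )
    else:
        v.append(
            Violation(
                "nonuniform_phantom",
                "non-uniform phantom: verify that sampled regions are uniform and span the axial extent",
                severity="info",
            )
        )
    return v


# ---------------------------------------------------------------------------
# serialization

def spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "name": spec.name,
        "kind": spec.kind,
        "body_volume_l": spec.body_volume_l,
        "axial_length_mm": spec.axial_length_mm,
        "body_shape": spec.body_shape,
        "cylinder_diameter_mm": spec.cylinder_diameter_mm,
        "body_semi_axes_mm": list(spec.body_semi_axes_mm) if spec.body_semi_axes_mm else None,
        "spheres": [
            {
                "inner_diameter_mm": s.inner_diameter_mm,
                "center_mm": list(s.center_mm),
                "wall_thickness_mm": s.wall_thickness_mm,
            }
            for s in spec.spheres
        ],
        "cold_inserts": [
            {
                "shape": c.shape,
                "density_class": c.density_class,
                "diameter_mm": c.diameter_mm,
                "center_xy_mm": list(c.center_xy_mm),
                "z_range_mm": list(c.z_range_mm) if c.z_range_mm else None,
            }
            for c in spec.cold_inserts
        ],
    }


def spec_from_dict(d: dict) -> PhantomSpec:
    return PhantomSpec(
        name=d["name"],
        kind=d["kind"],
        body_volume_l=float(d["body_volume_l"]),
        axial_length_mm=float(d["axial_length_mm"]),
        body_shape=d["body_shape"],
        spheres=tuple(
            SphereInsert(
                float(s["inner_diameter_mm"]),
                tuple(float(x) for x in s["center_mm"]),
                float(s.get("wall_thickness_mm", 1.0)),
            )
            for s in d.get("spheres", [])
        ),
        cold_inserts=tuple(
            ColdInsert(
                shape=c.get("shape", "cylinder"),
                density_class=c.get("density_class", "lung"),
                diameter_mm=float(c["diameter_mm"]),
                center_xy_mm=tuple(float(x) for x in c.get("center_xy_mm", (0.0, 0.0))),
                z_range_mm=tuple(float(x) for x in c["z_range_mm"]) if c.get("z_range_mm") else None,
            )
            for c in d.get("cold_inserts", [])
        ),
        cylinder_diameter_mm=(
            float(d["cylinder_diameter_mm"]) if d.get("cylinder_diameter_mm") is not None else None
        ),
        body_semi_axes_mm=(
            tuple(float(x) for x in d["body_semi_axes_mm"])
            if d.get("body_semi_axes_mm") is not None
            else None
        ),
    )


def save_phantom_json(spec: PhantomSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec_to_dict(spec), indent=2, sort_keys=True))


def load_phantom_json(path: str | Path) -> PhantomSpec:
    return spec_from_dict(json.loads(Path(path).read_text()))
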