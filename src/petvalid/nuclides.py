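"""Radionuclide registry and exponential decay correction.

All ground-truth activity concentrations in a phantom validation trace back
to radionuclide-calibrator assays decay-corrected to scan time, so the decay
arithmetic here underpins every other module.

Half-lives are stored in minutes.  The registry covers the positron emitters
in routine clinical-trial use: F-18 and Ga-68 (the quarterly-validation
nuclides) and the longer-lived Cu-64, Zr-89 and I-124.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

from .errors import ConfigurationError

__all__ = ["Radionuclide", "NUCLIDE_REGISTRY", "get_nuclide", "decay_correct"]


@dataclass(frozen=True)
class Radionuclide:
    """A positron-emitting radionuclide identified by name and half-life.

    Parameters
    ----------
    name :
        Canonical identifier, e.g. ``"F-18"``.
    half_life_min :
        Physical half-life in minutes; must be positive.
    """

    name: str
    half_life_min: float

    def __post_init__(self) -> None:
        if not self.half_life_min > 0:
            raise ConfigurationError(
                f"half-life must be positive, got {self.half_life_min} for {self.name!r}"
            )


#: Canonical registry.  Cu-64 12.7 h, Zr-89 3.25 d and I-124 4.2 d; F-18 and
#: Ga-68 use the standard evaluated values.
NUCLIDE_REGISTRY: dict[str, Radionuclide] = {
    "F-18": Radionuclide("F-18", 109.771),
    "Ga-68": Radionuclide("Ga-68", 67.71),
    "Cu-64": Radionuclide("Cu-64", 12.7 * 60.0),
    "Zr-89": Radionuclide("Zr-89", 3.25 * 24.0 * 60.0),
    "I-124": Radionuclide("I-124", 4.2 * 24.0 * 60.0),
}

_ALIASES = {n.replace("-", "").upper(): n for n in NUCLIDE_REGISTRY}


def get_nuclide(name: str) -> Radionuclide:
    """Look up a radionuclide by name; accepts ``F-18``, ``F18``, ``f-18`` etc."""
    key = name.strip().replace("-", "").replace("_", "").upper()
    try:
        return NUCLIDE_REGISTRY[_ALIASES[key]]
    except KeyError:
        known = ", ".join(sorted(NUCLIDE_REGISTRY))
        raise ConfigurationError(f"unknown radionuclide {name!r}; registry: {known}") from None


def decay_correct(
    activity_mbq: float,
    from_time: datetime,
    to_time: datetime,
    nuclide: Radionuclide,
) -> float:
    """Decay-correct an activity from ``from_time`` to ``to_time``.

    Returns ``activity × 2^(−Δt/T½)`` with Δt = to_time − from_time.
    Correction backwards in time (Δt < 0) is permitted and is the exact
    inverse of forward correction.
    """
    if not nuclide.half_life_min > 0:  # defensive; dataclass already checks
        raise ConfigurationError("nonpositive half-life")
    dt_min = (to_time - from_time).total_seconds() / 60.0
    return activity_mbq * 2.0 ** (-dt_min / nuclide.half_life_min)
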