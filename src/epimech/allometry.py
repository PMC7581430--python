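"""Allometric scaling of stylopod diameter and growth-plate pressure.

Across terrestrial tetrapods, stylopod (femur/humerus) diameter D scales
with body mass BM as a power law D = k·BMᵃ.  Published exponents vary with
the taxa sampled: 0.366 (ungulates), 0.3944 (insectivores + rodents) and
0.364 with k = 1.26 for the combined quadruped data set.  Since the load
on a growth plate scales with BM and its cross-section with D², the
pressure scales as BM^(1−2a): a thousandfold body-mass increase raises
growth-plate pressure roughly four- to seven-fold under these exponents,
whereas a = 0.5 would compensate pressure completely.

Units of BM and D in the printed coefficient are not stated; only ratios
of these quantities are unit-safe, and all fold-change operations here
use ratios exclusively.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AllometricLaw",
    "PRESETS",
    "stylopod_diameter",
    "pressure_fold",
    "compensation_diameter_fold",
    "report_fold",
]


@dataclass(frozen=True)
class AllometricLaw:
    """Power law D = k·BMᵃ with coefficient k and scaling exponent a."""

    k: float = 1.26
    a: float = 0.364
    name: str = "combined"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("coefficient k must be > 0")
        if not 0.0 < self.a <= 1.0:
            raise ValueError("scaling exponent a must be in (0, 1]")


PRESETS = {
    "ungulates": AllometricLaw(k=1.0, a=0.366, name="ungulates"),
    "insectivores_rodents": AllometricLaw(k=1.0, a=0.3944, name="insectivores_rodents"),
    "combined": AllometricLaw(k=1.26, a=0.364, name="combined"),
    "full_compensation": AllometricLaw(k=1.0, a=0.5, name="full_compensation"),
}


def stylopod_diameter(body_mass: float, law: AllometricLaw = PRESETS["combined"]) -> float:
    """D = k·BMᵃ (unit-agnostic; see module note on units)."""
    if body_mass <= 0:
        raise ValueError("body mass must be > 0")
    return law.k * body_mass**law.a


def pressure_fold(mass_ratio: float, a: float) -> float:
    """Growth-plate pressure fold-change for a body-mass ratio.

    Pressure ∝ BM / D² ∝ BM^(1−2a); a = 0.5 gives exact compensation
    (fold 1) for any ratio.
    """
    if mass_ratio <= 0:
        raise ValueError("mass ratio must be > 0")
    return mass_ratio ** (1.0 - 2.0 * a)


def compensation_diameter_fold(
    body_mass: float,
    law_actual: AllometricLaw = PRESETS["combined"],
    anchor_mass: float = 1.0,
) -> float:
    """Extra diameter multiplier needed for full pressure compensation.

    (BM/anchor)^(0.5 − a): how much wider every weight-bearing section
    would have to be at BM, relative to the actual allometry, to keep the
    pressure equal to its value at the anchor mass.
    """
    if body_mass <= 0 or anchor_mass <= 0:
        raise ValueError("masses must be > 0")
    return (body_mass / anchor_mass) ** (0.5 - law_actual.a)


def report_fold(value: float, ndigits: int = 1) -> float:
    """Reporting-layer rounding: one decimal, round-half-even."""
    return round(value, ndigits)
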