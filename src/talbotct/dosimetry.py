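"""Dose bookkeeping for grating-interferometer CT scans.

Converts entrance-skin dosimeter readings to free-air dose, models detector
quantum efficiency of silicon sensors, and scales a measured air dose to
the "feasible" dose an efficiency-optimized setup would need: a detector
with higher DQE and gratings on thinner silicon wafer supports.

The DQE model here is the zero-frequency absorbed fraction: the fraction
of incident photons undergoing an energy-depositing interaction
(photoelectric + Compton) in the sensor layer.  Coherent scattering only
redirects the photon without depositing energy, so it is excluded from the
DQE coefficient but included in wafer transmission, where any interaction
removes a photon from the useful beam.

Not modelled (documented limitation): the analyzer grating G2 absorbs
roughly half of the photons behind the sample, which effectively doubles
the dose of a grating-based attenuation image relative to a conventional
scan; the actual-to-feasible scaling used here deliberately leaves that
factor out since both scenarios keep G2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .optics import (
    SILICON,
    CoefficientKind,
    MaterialTable,
    attenuation_coefficient,
)


class SkinToAirMode(str, Enum):
    DIVIDE = "divide"
    MULTIPLY = "multiply"


@dataclass(frozen=True)
class FeasibilityScenario:
    """Premises of the feasible-dose calculation.

    target_dqe: DQE of an efficiency-optimized detector (default 0.70).
    Wafer thicknesses in micrometre: the actual grating substrates versus
    the thinnest technically feasible ones.  n_gratings counts the silicon
    wafers in the beam (2 for a two-grating synchrotron bench, 3 for a
    Talbot-Lau tube bench).
    """

    target_dqe: float = 0.70
    wafer_thickness_actual_um: float = 500.0
    wafer_thickness_feasible_um: float = 100.0
    n_gratings: int = 3
    energy_kev: float = 23.0
    material: MaterialTable = SILICON

    def __post_init__(self):
        if not 0.0 < self.target_dqe <= 1.0:
            raise ValueError("target DQE must be in (0, 1]")
        if self.wafer_thickness_feasible_um > self.wafer_thickness_actual_um:
            raise ValueError("feasible wafer must not be thicker than actual")
        if self.n_gratings not in (2, 3):
            raise ValueError("n_gratings must be 2 or 3")


@dataclass(frozen=True)
class DoseRecord:
    """Actual and feasible free-air dose with the assumed uncertainty band."""

    actual_air_dose_gy: float
    feasible_air_dose_gy: float
    uncertainty_fraction: float = 0.25

    def __post_init__(self):
        if self.actual_air_dose_gy < 0 or self.feasible_air_dose_gy < 0:
            raise ValueError("doses must be non-negative")
        if self.feasible_air_dose_gy > self.actual_air_dose_gy:
            raise ValueError("feasible dose must not exceed the actual dose")


def air_dose_from_skin(
    skin_reading_gy: float,
    factor: float = 1.4,
    mode: SkinToAirMode | str = SkinToAirMode.DIVIDE,
) -> float:
    """Convert an entrance-skin dosimeter reading to free-air dose.

    The conversion factor (1.4 for the dosimeter used) relates entrance
    skin dose to dose in free air; the direction of the conversion is
    instrument-specific, so it is an explicit mode rather than a guess.
    """
    if skin_reading_gy < 0:
        raise ValueError("dosimeter reading must be non-negative")
    if not factor > 0:
        raise ValueError("conversion factor must be positive")
    mode = SkinToAirMode(mode)
    if mode is SkinToAirMode.DIVIDE:
        return skin_reading_gy / factor
    return skin_reading_gy * factor


def absorbed_fraction(
    thickness_um: float,
    energy_kev: float,
    material: MaterialTable = SILICON,
    kind: CoefficientKind | str = CoefficientKind.ENERGY_DEPOSIT,
) -> float:
    """Fraction of photons interacting in a layer: 1 - exp(-mu * t)."""
    if thickness_um < 0:
        raise ValueError("thickness must be non-negative")
    mu = attenuation_coefficient(material, energy_kev, kind)
    return 1.0 - math.exp(-mu * thickness_um * 1e-4)


def silicon_dqe(thickness_um: float, energy_kev: float) -> float:
    """Zero-frequency DQE of a direct-detection silicon sensor.

    Absorbed fraction of the sensor layer via the energy-depositing
    (photoelectric + Compton) coefficient; 450 um at 23 keV gives 0.25.
    """
    return absorbed_fraction(
        thickness_um, energy_kev, SILICON, CoefficientKind.ENERGY_DEPOSIT
    )


def scaled_reference_dqe(
    reference_dqe: float, f_reference: float, f_actual: float
) -> float:
    """Scale a published DQE to a different converter thickness.

    Used for scintillator-based cameras where the converter's absorbed
    fraction changed between the published characterization and the actual
    screen: DQE_actual = DQE_ref * f_actual / f_reference, with both f the
    absorbed fractions of the respective converters (supplied by the
    caller; the converter material is not always published).
    """
    for name, v in (
        ("reference_dqe", reference_dqe),
        ("f_reference", f_reference),
        ("f_actual", f_actual),
    ):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must be in (0, 1]")
    out = reference_dqe * f_actual / f_reference
    if out > 1.0:
        raise ValueError("scaled DQE exceeds 1; inconsistent fractions")
    return out


def wafer_transmission(
    thickness_um: float,
    energy_kev: float,
    material: MaterialTable = SILICON,
) -> float:
    """Photon transmission of a grating wafer: exp(-mu_total * t)."""
    if thickness_um < 0:
        raise ValueError("thickness must be non-negative")
    mu = attenuation_coefficient(material, energy_kev, CoefficientKind.TOTAL)
    return math.exp(-mu * thickness_um * 1e-4)


def feasible_dose(
    actual_dose_gy: float,
    actual_dqe: float,
    scenario: FeasibilityScenario = FeasibilityScenario(),
) -> DoseRecord:
    """Scale a measured air dose to an efficiency-optimized scenario.

    The scan needs a fixed number of detected photons, so the required dose
    scales with the inverse DQE and with the inverse transmission of every
    grating wafer in the beam:

        feasible = actual * (DQE_actual / DQE_target)
                          * [T(t_actual) / T(t_feasible)] ** n_gratings

    The result carries the assumed +-25% uncertainty band of the underlying
    dosimetry (dosimeter energy dependence and calibration), quoted as a
    fraction, not re-derived.
    """
    if not 0.0 < actual_dqe <= 1.0:
        raise ValueError("actual DQE must be in (0, 1]")
    if actual_dose_gy < 0:
        raise ValueError("actual dose must be non-negative")
    t_ratio = wafer_transmission(
        scenario.wafer_thickness_actual_um, scenario.energy_kev, scenario.material
    ) / wafer_transmission(
        scenario.wafer_thickness_feasible_um, scenario.energy_kev, scenario.material
    )
    feasible = (
        actual_dose_gy
        * (actual_dqe / scenario.target_dqe)
        * t_ratio**scenario.n_gratings
    )
    return DoseRecord(
        actual_air_dose_gy=actual_dose_gy, feasible_air_dose_gy=feasible
    )
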