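"""X-ray optics for Talbot and Talbot-Lau grating interferometers.

Covers the desk math behind an interferometer design table: photon
wavelength, attenuation coefficients of the grating/sensor materials, the
fractional Talbot distance of a phase grating, and the cone-beam
(Talbot-Lau) geometry that fixes the analyzer period, inter-grating
distance and magnification from the source-grating period.

Units follow bench conventions: energies in keV, wavelengths in angstrom,
grating periods in micrometre, distances in millimetre, linear attenuation
coefficients in 1/cm.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
import numpy as np

#: hc in keV * angstrom; divides energy to give wavelength.
HC_KEV_ANGSTROM = 12.39842


class ShiftType(str, Enum):
    """Phase shift imprinted by the phase grating G1 at design energy."""

    PI = "pi"
    PI_HALF = "pi_half"


class CoefficientKind(str, Enum):
    """Which partial attenuation coefficient to evaluate.

    ``TOTAL`` includes coherent (Rayleigh) scattering and governs how many
    photons survive an absorber unscattered-or-not; ``PHOTOELECTRIC`` counts
    photoabsorption only; ``INCOHERENT`` is Compton scattering;
    ``ENERGY_DEPOSIT`` is photoelectric + incoherent, i.e. the interactions
    that leave energy in a thin sensor (coherent scattering merely redirects
    the photon).
    """

    TOTAL = "total"
    PHOTOELECTRIC = "photoelectric"
    INCOHERENT = "incoherent"
    ENERGY_DEPOSIT = "energy_deposit"


@dataclass(frozen=True)
class MaterialTable:
    """Mass-attenuation grid of one material.

    Parameters
    ----------
    name : str
        Material label.
    density : float
        Bulk density in g/cm^3.
    energies_kev : tuple of float
        Strictly increasing photon energies of the grid.
    mu_rho_total : tuple of float
        Total mass attenuation coefficient (with coherent), cm^2/g.
    mu_rho_photoelectric : tuple of float
        Photoelectric mass attenuation coefficient, cm^2/g.
    mu_rho_incoherent : tuple of float
        Incoherent (Compton) mass attenuation coefficient, cm^2/g.
    """

    name: str
    density: float
    energies_kev: tuple
    mu_rho_total: tuple
    mu_rho_photoelectric: tuple
    mu_rho_incoherent: tuple

    def __post_init__(self):
        e = np.asarray(self.energies_kev, dtype=float)
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("grid energies must be strictly increasing")
        for attr in ("mu_rho_total", "mu_rho_photoelectric", "mu_rho_incoherent"):
            vals = np.asarray(getattr(self, attr), dtype=float)
            if vals.shape != e.shape:
                raise ValueError(f"{attr} must match the energy grid length")
            if np.any(vals <= 0):
                raise ValueError(f"{attr} must be positive everywhere")
        pe = np.asarray(self.mu_rho_photoelectric, dtype=float)
        tot = np.asarray(self.mu_rho_total, dtype=float)
        if np.any(pe > tot):
            raise ValueError("photoelectric coefficient exceeds total")
        if self.density <= 0:
            raise ValueError("density must be positive")

    def column(self, kind: CoefficientKind) -> np.ndarray:
        kind = CoefficientKind(kind)
        if kind is CoefficientKind.TOTAL:
            return np.asarray(self.mu_rho_total, dtype=float)
        if kind is CoefficientKind.PHOTOELECTRIC:
            return np.asarray(self.mu_rho_photoelectric, dtype=float)
        if kind is CoefficientKind.INCOHERENT:
            return np.asarray(self.mu_rho_incoherent, dtype=float)
        return np.asarray(self.mu_rho_photoelectric, dtype=float) + np.asarray(
            self.mu_rho_incoherent, dtype=float
        )


# Silicon grid, NIST/XCOM-derived (see docs/methods.md for provenance):
# totals from the NIST mass-attenuation tables, photoelectric from
# Cromer-Liberman f'', incoherent at XCOM magnitudes.  Values in cm^2/g.
SILICON = MaterialTable(
    name="silicon",
    density=2.33,
    energies_kev=(10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0),
    mu_rho_total=(33.89, 10.34, 4.464, 2.38, 1.436, 0.977, 0.7012),
    mu_rho_photoelectric=(32.41, 9.599, 3.998, 2.012, 1.142, 0.705, 0.463),
    mu_rho_incoherent=(0.080, 0.110, 0.130, 0.143, 0.152, 0.158, 0.162),
)


def load_material_csv(path, *, name: str, density: float) -> MaterialTable:
    """Load a material grid from CSV.

    Expects a header row with columns ``energy_keV``, ``mu_rho_total``,
    ``mu_rho_photoelectric`` and optionally ``mu_rho_incoherent`` (defaults
    to total - photoelectric when absent, folding coherent scattering into
    the incoherent column).
    """
    rows = []
    with open(Path(path), newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"energy_keV", "mu_rho_total", "mu_rho_photoelectric"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"material CSV needs header columns {sorted(required)}"
            )
        has_incoh = "mu_rho_incoherent" in reader.fieldnames
        for row in reader:
            e = float(row["energy_keV"])
            tot = float(row["mu_rho_total"])
            pe = float(row["mu_rho_photoelectric"])
            inc = float(row["mu_rho_incoherent"]) if has_incoh else tot - pe
            rows.append((e, tot, pe, inc))
    rows.sort()
    e, tot, pe, inc = zip(*rows)
    return MaterialTable(
        name=name,
        density=density,
        energies_kev=e,
        mu_rho_total=tot,
        mu_rho_photoelectric=pe,
        mu_rho_incoherent=inc,
    )


def wavelength(energy_kev: float) -> float:
    """Photon wavelength in angstrom for an energy in keV (lambda = hc/E)."""
    if not energy_kev > 0:
        raise ValueError(f"energy must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


def attenuation_coefficient(
    material: MaterialTable,
    energy_kev: float,
    kind: CoefficientKind | str = CoefficientKind.TOTAL,
) -> float:
    """Linear attenuation coefficient in 1/cm at ``energy_kev``.

    The mass coefficient is interpolated log-log between the bracketing
    grid points (cross sections are near power-law over tens of keV) and
    multiplied by the material density.  Queries outside the grid raise:
    no extrapolation.
    """
    e = np.asarray(material.energies_kev, dtype=float)
    if not (e[0] <= energy_kev <= e[-1]):
        raise ValueError(
            f"energy {energy_kev} keV outside material grid "
            f"[{e[0]}, {e[-1]}] keV"
        )
    col = material.column(kind)
    mu_rho = float(
        np.exp(np.interp(np.log(energy_kev), np.log(e), np.log(col)))
    )
    return mu_rho * material.density


@dataclass(frozen=True)
class InterferometerDesign:
    """Geometry and nominal performance of one grating interferometer.

    ``p0`` and ``l`` are None for plane-wave (parallel-beam synchrotron)
    designs, where the magnification is exactly 1.
    """

    energy_kev: float
    shift_type: ShiftType
    p1_um: float
    p2_um: float
    talbot_order: int
    d_mm: float
    p0_um: float | None = None
    l_mm: float | None = None
    magnification: float = 1.0
    design_visibility: float = 0.30

    def __post_init__(self):
        if self.p0_um is None:
            if abs(self.magnification - 1.0) > 1e-12:
                raise ValueError("plane-wave design requires M = 1")
        else:
            # cone geometry: l/d = p0/p2 and p2 = M * self-image period
            if self.l_mm is None:
                raise ValueError("cone design requires l")
            if abs(self.l_mm / self.d_mm - self.p0_um / self.p2_um) > 0.01 * (
                self.p0_um / self.p2_um
            ):
                raise ValueError("inconsistent cone geometry: l/d != p0/p2")
            s = _self_image_period(self.p1_um, self.shift_type)
            if abs(self.p2_um - self.magnification * s) > 0.01 * self.p2_um:
                raise ValueError("p2 inconsistent with M * self-image period")
        if not 0.0 < self.design_visibility <= 1.0:
            raise ValueError("design visibility must be in (0, 1]")

    @property
    def wavelength_angstrom(self) -> float:
        return wavelength(self.energy_kev)

    def phase_sensitivity_um(self) -> float:
        """lambda * d / p2 in micrometre.

        Multiplies the transverse gradient of the wavefront phase (rad/um)
        to give the measured stepping-curve phase shift in radians.
        """
        lam_um = self.wavelength_angstrom * 1e-4
        return lam_um * (self.d_mm * 1e3) / self.p2_um


def _self_image_period(p1_um: float, shift_type: ShiftType) -> float:
    # A pi-shifting grating self-images at half its period; pi/2 at full.
    shift_type = ShiftType(shift_type)
    return p1_um if shift_type is ShiftType.PI_HALF else p1_um / 2.0


def _check_order(order: int) -> int:
    order = int(order)
    if order <= 0 or order % 2 == 0:
        raise ValueError(f"fractional Talbot order must be odd positive, got {order}")
    return order


def talbot_distance(
    p1_um: float,
    energy_kev: float,
    order: int,
    shift_type: ShiftType | str,
) -> float:
    """Plane-wave fractional Talbot distance in mm.

    n * p1^2 / (2 lambda) for a pi/2 grating, n * p1^2 / (8 lambda) for a
    pi grating, with odd n.
    """
    order = _check_order(order)
    if p1_um <= 0:
        raise ValueError("p1 must be positive")
    shift_type = ShiftType(shift_type)
    lam_um = wavelength(energy_kev) * 1e-4
    denom = 2.0 if shift_type is ShiftType.PI_HALF else 8.0
    d_um = order * p1_um**2 / (denom * lam_um)
    return d_um * 1e-3


def talbot_lau_geometry(
    p0_um: float,
    p1_um: float,
    energy_kev: float,
    order: int,
    shift_type: ShiftType | str,
    design_visibility: float = 0.30,
) -> InterferometerDesign:
    """Solve the three-grating (Talbot-Lau) cone geometry.

    The source grating G0 at distance l upstream of G1 magnifies the G1
    self-image (period s) by M = p0 / (p0 - s) onto the analyzer G2, so
    p2 = M*s, d = M * plane-wave Talbot distance and l = d * p0 / p2.
    ``p0_um=math.inf`` collapses to the plane-wave two-grating limit.
    """
    order = _check_order(order)
    shift_type = ShiftType(shift_type)
    s = _self_image_period(p1_um, shift_type)
    d_plane = talbot_distance(p1_um, energy_kev, order, shift_type)
    if math.isinf(p0_um):
        return InterferometerDesign(
            energy_kev=energy_kev,
            shift_type=shift_type,
            p1_um=p1_um,
            p2_um=s,
            talbot_order=order,
            d_mm=d_plane,
            design_visibility=design_visibility,
        )
    if not p0_um > s:
        raise ValueError(
            f"no cone solution: p0 ({p0_um} um) must exceed the "
            f"self-image period ({s} um)"
        )
    magnification = p0_um / (p0_um - s)
    p2 = magnification * s
    d = magnification * d_plane
    l = d * p0_um / p2
    return InterferometerDesign(
        energy_kev=energy_kev,
        shift_type=shift_type,
        p0_um=p0_um,
        p1_um=p1_um,
        p2_um=p2,
        talbot_order=order,
        d_mm=d,
        l_mm=l,
        magnification=magnification,
        design_visibility=design_visibility,
    )


def tube_design(design_visibility: float = 0.30) -> InterferometerDesign:
    """Three-grating tube-source design: 23 keV, p0=10, p1=3.51 um, 3rd
    order, pi/2 grating."""
    return talbot_lau_geometry(
        10.0, 3.51, 23.0, 3, ShiftType.PI_HALF, design_visibility
    )


def synchrotron_design(design_visibility: float = 0.30) -> InterferometerDesign:
    """Two-grating plane-wave design: 35 keV, p1=4.79 um, 5th order, pi
    grating."""
    return talbot_lau_geometry(
        math.inf, 4.79, 35.0, 5, ShiftType.PI, design_visibility
    )
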