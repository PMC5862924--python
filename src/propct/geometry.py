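"""Effective cone-beam geometry for propagation-based phase-contrast imaging.

A point-source cone-beam setup with source-to-object distance ``z01`` and
source-to-detector distance ``z02`` is equivalent, via the Fresnel scaling
theorem, to a parallel-beam setup with

* geometric magnification      ``M = z02 / z01``
* effective propagation length ``z_eff = z01 * z12 / z02``  (z12 = z02 - z01)
* effective (demagnified) pixel ``p_eff = p / M``

The dimensionless Fresnel number ``F_eff = p_eff**2 / (z_eff * lambda)``
locates the imaging regime: F >> 1 is near-contact absorption contrast,
F ~< 1 is the direct-contrast (edge-enhancement) regime where single-distance
phase retrieval applies.

Units are fixed package-wide: distances in mm, pixel pitches in um, photon
energy in keV, wavelength in um.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "HC_EV_UM",
    "ConeBeamGeometry",
    "InvalidGeometryError",
    "magnification",
    "effective_distance",
    "effective_pixel",
    "wavelength",
    "fresnel_number",
]

#: Planck constant times speed of light, eV * um (CODATA-rounded). Fixed so
#: that every derived wavelength and Fresnel number is bit-reproducible.
HC_EV_UM = 1.23984193


class InvalidGeometryError(ValueError):
    """Raised when a cone-beam geometry violates its physical constraints."""


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Cone-beam scan geometry.

    Parameters
    ----------
    z01_mm:
        Source-to-object distance, mm. Must be positive.
    z02_mm:
        Source-to-detector distance, mm. Must satisfy ``z02 >= z01``.
    pixel_um:
        Physical detector pixel pitch, um.
    energy_kev:
        Photon energy, keV.
    source_fwhm_um:
        Optional source spot FWHM, um, used for penumbral blur modelling.
    """

    z01_mm: float
    z02_mm: float
    pixel_um: float
    energy_kev: float
    source_fwhm_um: float = 0.0

    def __post_init__(self) -> None:
        if not self.z01_mm > 0:
            raise InvalidGeometryError(f"z01 must be positive, got {self.z01_mm}")
        if self.z02_mm < self.z01_mm:
            raise InvalidGeometryError(
                f"z02 ({self.z02_mm}) must be >= z01 ({self.z01_mm})"
            )
        if not self.pixel_um > 0:
            raise InvalidGeometryError(f"pixel pitch must be positive, got {self.pixel_um}")
        if not self.energy_kev > 0:
            raise InvalidGeometryError(f"energy must be positive, got {self.energy_kev}")
        if self.source_fwhm_um < 0:
            raise InvalidGeometryError("source FWHM must be non-negative")

    @property
    def z12_mm(self) -> float:
        """Object-to-detector distance, mm."""
        return self.z02_mm - self.z01_mm

    @property
    def magnification(self) -> float:
        return magnification(self)

    @property
    def effective_distance_mm(self) -> float:
        return effective_distance(self)

    @property
    def effective_pixel_um(self) -> float:
        return effective_pixel(self)

    @property
    def wavelength_um(self) -> float:
        return wavelength(self.energy_kev)

    @property
    def fresnel_number(self) -> float:
        return fresnel_number(self)

    def summary(self) -> dict:
        """All derived quantities as a plain dict (for tables / JSON)."""
        return {
            "z01_mm": self.z01_mm,
            "z02_mm": self.z02_mm,
            "z12_mm": self.z12_mm,
            "pixel_um": self.pixel_um,
            "energy_kev": self.energy_kev,
            "magnification": self.magnification,
            "z_eff_mm": self.effective_distance_mm,
            "p_eff_um": self.effective_pixel_um,
            "wavelength_um": self.wavelength_um,
            "fresnel_number": self.fresnel_number,
        }


def magnification(geom: ConeBeamGeometry) -> float:
    """Geometric magnification M = (z01 + z12) / z01 = z02 / z01 (>= 1)."""
    return geom.z02_mm / geom.z01_mm


def effective_distance(geom: ConeBeamGeometry) -> float:
    """Effective parallel-beam propagation distance z01*z12/(z01+z12), mm."""
    return geom.z01_mm * geom.z12_mm / geom.z02_mm


def effective_pixel(geom: ConeBeamGeometry) -> float:
    """Effective (object-plane) pixel size p / M, um."""
    return geom.pixel_um / magnification(geom)


def wavelength(energy_kev: float) -> float:
    """Photon wavelength hc/E in um for E in keV."""
    if not energy_kev > 0:
        raise ValueError(f"energy must be positive, got {energy_kev}")
    return HC_EV_UM / (energy_kev * 1e3)


def fresnel_number(geom: ConeBeamGeometry) -> float:
    """Effective Fresnel number F_eff = p_eff**2 / (z_eff * lambda).

    Computed from full-precision intermediates (never from rounded printed
    values). Dimensionless; p_eff in um, z_eff converted mm -> um.
    """
    z_eff_um = effective_distance(geom) * 1e3
    if z_eff_um == 0:
        raise InvalidGeometryError(
            "Fresnel number is infinite at contact (z12 = 0)"
        )
    p_eff = effective_pixel(geom)
    return p_eff**2 / (z_eff_um * wavelength(geom.energy_kev))
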