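"""Light dosimetry and retinal-geometry arithmetic.

Converts stimulus power measured at the pupil into retinal irradiance,
scales power between eyes of different numerical aperture, converts visual
angle to retinal distance, and predicts expected cell counts from areal
density — the bookkeeping needed to compare stimulus light levels across
species and against exposure-safety limits.

Two retinal magnification conventions are in circulation for the mouse eye
and they are NOT mutually consistent; both are exposed rather than silently
resolved:

- ``UM_PER_DEG_DOSIMETRY`` (34.4 μm/deg): the value implied by standard
  mouse retinal irradiance calculations (20 μW over an 8° patch giving
  ~33.6 mW/cm²).
- ``UM_PER_DEG_FIELD`` (32.0 μm/deg): the value implied by equating a 5°
  scan to 160 μm of retina.

Callers must pick the geometry explicitly; results carry it as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalGeometry",
    "MOUSE_GEOMETRY_DOSIMETRY",
    "MOUSE_GEOMETRY_FIELD",
    "retinal_irradiance",
    "na_equivalent_power",
    "expected_cell_count",
    "deg_to_um",
]

UM_PER_DEG_DOSIMETRY = 34.4
UM_PER_DEG_FIELD = 32.0
MOUSE_NA = 0.49
HUMAN_NA = 0.24
#: ANSI Z136 maximum permissible exposure at 620 nm for an 8-hour human
#: exposure (documented constant for report annotation; not recomputed here)
ANSI_MPE_620NM_8H_UW = 40.0


@dataclass(frozen=True)
class OpticalGeometry:
    """Retinal magnification and numerical aperture of one eye."""

    um_per_deg: float
    numerical_aperture: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.um_per_deg) and self.um_per_deg > 0):
            raise ValueError("um_per_deg must be positive and finite")
        if not (np.isfinite(self.numerical_aperture) and self.numerical_aperture > 0):
            raise ValueError("numerical_aperture must be positive and finite")


MOUSE_GEOMETRY_DOSIMETRY = OpticalGeometry(UM_PER_DEG_DOSIMETRY, MOUSE_NA)
MOUSE_GEOMETRY_FIELD = OpticalGeometry(UM_PER_DEG_FIELD, MOUSE_NA)
HUMAN_GEOMETRY = OpticalGeometry(288.0, HUMAN_NA)


def retinal_irradiance(
    power_uw: float,
    patch_diameter_deg: float,
    geometry: OpticalGeometry = MOUSE_GEOMETRY_DOSIMETRY,
) -> float:
    """Retinal irradiance in mW/cm² from pupil power over a circular patch.

    irradiance = power / (π (d/2)²) with the patch diameter converted from
    degrees of visual angle to retinal centimeters via the geometry.
    """
    if power_uw < 0:
        raise ValueError("power must be >= 0")
    if patch_diameter_deg <= 0:
        raise ValueError("patch diameter must be > 0")
    radius_cm = (patch_diameter_deg / 2.0) * geometry.um_per_deg * 1e-4
    area_cm2 = np.pi * radius_cm**2
    return (power_uw * 1e-3) / area_cm2  # μW -> mW


def na_equivalent_power(
    power_uw: float, na_source: float, na_target: float
) -> float:
    """Power in the target eye giving the same retinal irradiance.

    Retinal irradiance scales with NA², so equivalent power scales with
    (NA_source / NA_target)².
    """
    if na_source <= 0 or na_target <= 0:
        raise ValueError("numerical apertures must be > 0")
    return power_uw * (na_source / na_target) ** 2


def expected_cell_count(
    density_per_mm2: float, field_um: tuple[float, float]
) -> tuple[float, int]:
    """Expected number of cells of a given areal density in one field.

    Returns both the exact product density x area(mm²) and its nearest
    integer.
    """
    if density_per_mm2 < 0:
        raise ValueError("density must be >= 0")
    w_um, h_um = field_um
    area_mm2 = (w_um * 1e-3) * (h_um * 1e-3)
    exact = density_per_mm2 * area_mm2
    return exact, int(round(exact))


def deg_to_um(extent_deg: float, geometry: OpticalGeometry) -> float:
    """Visual angle (degrees) to retinal distance (micrometers)."""
    if not np.isfinite(extent_deg):
        raise ValueError("extent must be finite")
    return extent_deg * geometry.um_per_deg
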