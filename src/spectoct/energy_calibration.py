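"""Bragg-angle / photon-energy conversion for a spherically bent crystal analyser.

A Johann-type spectrometer monochromatises the polychromatic tube beam with a
spherically bent crystal on a Rowland circle whose diameter equals the crystal
bending radius.  The photon energy selected at Bragg angle ``theta`` follows
Bragg's law ``n·lambda = 2 d sin(theta)`` with ``n = 1``; in energy units

    E [keV] = K / (2 d sin(theta)),   K = h c = 12.39842 keV·Å.

All public angles are in degrees, energies in keV and lengths in the units
stated per field — no implicit unit conversions at API boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "HC_KEV_ANGSTROM",
    "SI_LATTICE_ANGSTROM",
    "CrystalReflection",
    "SpectrometerGeometry",
    "bragg_energy",
    "bragg_angle",
    "source_to_analyser_distance",
]

#: Conversion constant h*c in keV·Å.
HC_KEV_ANGSTROM = 12.39842

#: Silicon lattice constant at room temperature, Å.
SI_LATTICE_ANGSTROM = 5.4309


@dataclass(frozen=True)
class CrystalReflection:
    """A crystal reflection (h k l) of a cubic lattice.

    Parameters
    ----------
    lattice_constant:
        Cubic lattice constant ``a`` in Å.
    miller_indices:
        Miller indices ``(h, k, l)``; must not all be zero.
    """

    lattice_constant: float = SI_LATTICE_ANGSTROM
    miller_indices: tuple[int, int, int] = (9, 5, 3)

    def __post_init__(self) -> None:
        if self.lattice_constant <= 0:
            raise ValueError(f"lattice_constant must be > 0, got {self.lattice_constant}")
        if all(m == 0 for m in self.miller_indices):
            raise ValueError("miller_indices (0, 0, 0) does not define a reflection")

    @property
    def d_spacing(self) -> float:
        """Interplanar spacing ``a / sqrt(h^2 + k^2 + l^2)`` in Å."""
        h, k, l = self.miller_indices
        return self.lattice_constant / math.sqrt(h * h + k * k + l * l)

    @property
    def backscattering_energy(self) -> float:
        """Minimum reachable photon energy ``K / (2 d)`` in keV (theta = 90°)."""
        return HC_KEV_ANGSTROM / (2.0 * self.d_spacing)


def _si_953() -> CrystalReflection:
    return CrystalReflection(SI_LATTICE_ANGSTROM, (9, 5, 3))


@dataclass(frozen=True)
class SpectrometerGeometry:
    """Rowland-circle geometry of the Johann spectrometer.

    Distances in metres.  The secondary source (the analyser focus) feeds the
    sample and detector downstream; ``secondary_source_to_sample`` is
    configurable because only the source-to-detector distance is typically
    surveyed.
    """

    bending_radius: float = 0.5
    secondary_source_to_detector: float = 0.21
    secondary_source_to_sample: float = 0.19
    bragg_angle_range: tuple[float, float] = (73.01, 77.47)

    def __post_init__(self) -> None:
        if self.bending_radius <= 0:
            raise ValueError(f"bending_radius must be > 0, got {self.bending_radius}")
        for name in ("secondary_source_to_detector", "secondary_source_to_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        lo, hi = self.bragg_angle_range
        if not (0.0 < lo < 90.0 and 0.0 < hi < 90.0):
            raise ValueError(f"bragg_angle_range must lie in (0, 90), got {self.bragg_angle_range}")

    @property
    def magnification(self) -> float:
        """Geometric magnification sample → detector for a point secondary source."""
        if self.secondary_source_to_sample == 0:
            raise ValueError("secondary_source_to_sample is 0; magnification undefined")
        return self.secondary_source_to_detector / self.secondary_source_to_sample


def _check_angle(theta_deg: float) -> None:
    if not 0.0 < theta_deg < 90.0:
        raise ValueError(f"Bragg angle must be in (0, 90) degrees, got {theta_deg}")


def bragg_energy(theta_deg: float, reflection: CrystalReflection | None = None) -> float:
    """Photon energy (keV) diffracted at Bragg angle ``theta_deg`` (degrees).

    Strictly decreasing in ``theta_deg`` on (0°, 90°); the 90° limit is the
    backscattering minimum ``K / (2 d)``.
    """
    if reflection is None:
        reflection = _si_953()
    _check_angle(theta_deg)
    return HC_KEV_ANGSTROM / (2.0 * reflection.d_spacing * math.sin(math.radians(theta_deg)))


def bragg_angle(energy_kev: float, reflection: CrystalReflection | None = None) -> float:
    """Bragg angle (degrees) that selects ``energy_kev`` — exact inverse of
    :func:`bragg_energy`.

    Raises ``ValueError`` if the energy lies below the backscattering minimum
    (``sin(theta)`` would exceed 1).
    """
    if reflection is None:
        reflection = _si_953()
    if energy_kev <= 0:
        raise ValueError(f"energy must be > 0 keV, got {energy_kev}")
    s = HC_KEV_ANGSTROM / (2.0 * reflection.d_spacing * energy_kev)
    if s > 1.0:
        raise ValueError(
            f"{energy_kev} keV is below the backscattering minimum "
            f"{reflection.backscattering_energy:.5f} keV for this reflection"
        )
    return math.degrees(math.asin(s))


def source_to_analyser_distance(
    theta_deg: float, geometry: SpectrometerGeometry | None = None
) -> float:
    """Primary source → analyser distance ``R sin(theta)`` on the Rowland
    circle, in cm.

    This is the ideal Johann geometry value; surveyed stage positions on a
    real instrument can differ by a few mm.
    """
    if geometry is None:
        geometry = SpectrometerGeometry()
    _check_angle(theta_deg)
    return geometry.bending_radius * math.sin(math.radians(theta_deg)) * 100.0
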