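"""Confocal observation-volume geometry.

The detection profile is the standard 3D-Gaussian approximation of a
confocal point-spread function,

    B(x, y, z) = exp(-2 (x^2 + y^2) / w0^2) * exp(-2 z^2 / z0^2),

with lateral 1/e^2 radius ``w0`` and axial 1/e^2 radius ``z0``.  The
structure parameter ``S = z0 / w0`` describes the elongation of the
volume along the optical axis.  Membrane measurements place the
diffusing species in the ``z = 0`` plane, where only the lateral part
of the profile matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BeamProfile", "DEFAULT_BEAM"]


@dataclass(frozen=True)
class BeamProfile:
    """Gaussian observation volume with lateral radius ``w0`` and axial radius ``z0`` (um)."""

    w0: float
    z0: float

    def __post_init__(self) -> None:
        if not (self.w0 > 0):
            raise ValueError(f"w0 must be positive, got {self.w0}")
        if not (self.z0 > 0):
            raise ValueError(f"z0 must be positive, got {self.z0}")

    @classmethod
    def from_structure(cls, w0: float = 0.2, S: float = 5.0) -> "BeamProfile":
        """Build a profile from the lateral radius and structure parameter S = z0/w0."""
        if not (S > 0):
            raise ValueError(f"structure parameter S must be positive, got {S}")
        return cls(w0=w0, z0=S * w0)

    @property
    def S(self) -> float:
        """Structure parameter z0 / w0."""
        return self.z0 / self.w0

    def intensity(self, x, y, z=0.0):
        """Normalized detection profile B(r); equals 1 at the origin."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        return np.exp(
            -2.0 * (x * x + y * y) / self.w0**2 - 2.0 * z * z / self.z0**2
        )

    def psf_integral(self, dimensionality: int) -> float:
        """Integral of B over all space: area (um^2) in 2D, volume (um^3) in 3D."""
        _check_dim(dimensionality)
        lateral = (math.pi / 2.0) * self.w0**2
        if dimensionality == 2:
            return lateral
        return lateral * math.sqrt(math.pi / 2.0) * self.z0

    def psf_squared_integral(self, dimensionality: int) -> float:
        """Integral of B^2 over all space."""
        _check_dim(dimensionality)
        lateral = (math.pi / 4.0) * self.w0**2
        if dimensionality == 2:
            return lateral
        return lateral * math.sqrt(math.pi) / 2.0 * self.z0

    def contrast_gamma(self, dimensionality: int) -> float:
        """Profile contrast factor gamma = int(B^2) / int(B): 2^-3/2 in 3D, 1/2 in 2D."""
        return self.psf_squared_integral(dimensionality) / self.psf_integral(
            dimensionality
        )

    def effective_volume(self, dimensionality: int) -> float:
        """FCS effective volume (int B)^2 / int B^2."""
        return (
            self.psf_integral(dimensionality) ** 2
            / self.psf_squared_integral(dimensionality)
        )


def _check_dim(dimensionality: int) -> None:
    if dimensionality not in (2, 3):
        raise ValueError(f"dimensionality must be 2 or 3, got {dimensionality}")


#: Default water-immersion confocal geometry: w0 = 0.2 um, S = 5.
DEFAULT_BEAM = BeamProfile.from_structure(w0=0.2, S=5.0)
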