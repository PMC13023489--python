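"""Parametric post-dilation vessel/balloon geometries.

The geometry is an idealised, rotationally symmetric snapshot of a vessel
*after* balloon dilation: an annular wall, an optional annular plaque whose
inner radius tapers smoothly to the lumen radius at its axial ends, and a
thin balloon shell pressed flush against the innermost tissue surface
(plaque where present, otherwise the wall).  Stenosis rate follows the
clinical diameter-reduction convention: at the plaque throat,
``(lumen_radius - plaque_inner_radius) / lumen_radius`` equals the rate.

All lengths are in metres; ``z`` runs axially from the vessel inlet at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError

MM = 1e-3

__all__ = ["MM", "VesselDims", "StenosisGeometry", "build_geometry"]


@dataclass(frozen=True)
class VesselDims:
    """Dimensions of the idealised vessel/balloon configuration.

    Defaults are coronary-scale fixture values; the balloon shell thickness
    of 0.10 mm is the one printed device dimension.
    """

    lumen_radius: float = 1.5 * MM
    wall_thickness: float = 1.0 * MM
    vessel_length: float = 20.0 * MM
    plaque_half_length: float = 5.0 * MM
    balloon_thickness: float = 0.10 * MM
    balloon_length: float = 15.0 * MM

    def __post_init__(self) -> None:
        for name in (
            "lumen_radius",
            "wall_thickness",
            "vessel_length",
            "plaque_half_length",
            "balloon_thickness",
            "balloon_length",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise ValidationError(f"{name} must be strictly positive, got {value!r}")
        if self.plaque_half_length >= self.vessel_length / 2.0:
            raise ValidationError(
                "plaque_half_length must be smaller than half the vessel length"
            )
        if self.balloon_length > self.vessel_length:
            raise ValidationError("balloon_length must not exceed vessel_length")

    @property
    def outer_radius(self) -> float:
        return self.lumen_radius + self.wall_thickness


@dataclass(frozen=True)
class StenosisGeometry:
    """Axisymmetric post-dilation configuration of lumen, wall, plaque, balloon.

    The plaque occupies the annulus between :meth:`plaque_inner_radius` and
    the lumen radius over ``|z - z_mid| < plaque_half_length``; its thickness
    follows a cosine taper from the throat value ``stenosis_rate *
    lumen_radius`` down to zero at the shoulders.  The balloon shell occupies
    the ``balloon_thickness`` band immediately inside the contact surface.
    """

    dims: VesselDims
    stenosis_rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.stenosis_rate < 1.0):
            raise DomainError(
                f"stenosis_rate must lie in [0, 1), got {self.stenosis_rate!r}"
            )

    # -- axial landmarks ---------------------------------------------------
    @property
    def z_mid(self) -> float:
        return self.dims.vessel_length / 2.0

    @property
    def balloon_span(self) -> tuple[float, float]:
        half = self.dims.balloon_length / 2.0
        return (self.z_mid - half, self.z_mid + half)

    @property
    def plaque_span(self) -> tuple[float, float]:
        half = self.dims.plaque_half_length
        return (self.z_mid - half, self.z_mid + half)

    @property
    def has_plaque(self) -> bool:
        return self.stenosis_rate > 0.0

    # -- radial profiles ---------------------------------------------------
    def plaque_thickness(self, z):
        """Radial plaque thickness at axial position(s) ``z`` (cosine taper)."""
        z = np.asarray(z, dtype=float)
        if not self.has_plaque:
            return np.zeros_like(z)
        h = self.dims.plaque_half_length
        xi = (z - self.z_mid) / h
        peak = self.stenosis_rate * self.dims.lumen_radius
        thick = np.where(np.abs(xi) < 1.0, 0.5 * peak * (1.0 + np.cos(np.pi * xi)), 0.0)
        return thick

    def plaque_inner_radius(self, z):
        """Plaque inner radius r_p(z); equals the lumen radius where no plaque."""
        return self.dims.lumen_radius - self.plaque_thickness(z)

    def contact_radius(self, z):
        """Radius of the surface the inflated balloon presses against."""
        return self.plaque_inner_radius(z)

    def balloon_inner_radius(self, z):
        return self.contact_radius(z) - self.dims.balloon_thickness

    @property
    def throat_radius(self) -> float:
        return self.dims.lumen_radius * (1.0 - self.stenosis_rate)


def build_geometry(stenosis_rate: float, dims: VesselDims | None = None) -> StenosisGeometry:
    """Build a parametric post-dilation geometry.

    Parameters
    ----------
    stenosis_rate:
        Fractional diameter reduction at the plaque throat, in ``[0, 1)``.
        Zero yields a plain cylindrical tube (the ex vivo configuration).
    dims:
        Vessel/balloon dimensions; defaults to the documented fixture values.
    """
    if dims is None:
        dims = VesselDims()
    return StenosisGeometry(dims=dims, stenosis_rate=float(stenosis_rate))
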