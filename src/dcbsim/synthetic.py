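"""Fixture geometries and synthetic uptake measurements.

The in vitro uptake data behind the transfer-coefficient calibration come
from a bench study whose specimen dimensions are not part of this package;
fixtures here are documented coronary-scale stand-ins.  The measurement
generator runs the forward transfer model at a known coefficient and
applies multiplicative lognormal noise, so calibration can be exercised as
a parameter-recovery experiment with a controlled ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import AbsorptionMeasurement
from .errors import DomainError, ValidationError
from .geometry import StenosisGeometry, VesselDims, build_geometry
from .mesh import AxiMesh, mesh_geometry
from .transfer import TransportParams, simulate_absorption

__all__ = [
    "FIXTURE_RATES",
    "MeasurementNoiseModel",
    "make_fixture",
    "gen_measurements",
]

#: stenosis rate of each named fixture preset
FIXTURE_RATES = {"exvivo": 0.0, "s10": 0.10, "s30": 0.30, "s50": 0.50}


@dataclass(frozen=True)
class MeasurementNoiseModel:
    """Multiplicative lognormal noise: coefficient of variation plus seed."""

    cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValidationError("cv must be non-negative")

    def factors(self, n: int) -> np.ndarray:
        """``n`` unit-mean lognormal factors with the configured CV."""
        if self.cv == 0:
            return np.ones(n)
        rng = np.random.default_rng(self.seed)
        sigma = np.sqrt(np.log1p(self.cv**2))
        return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))


def make_fixture(preset: str, dims: VesselDims | None = None) -> StenosisGeometry:
    """Build one of the named fixture geometries.

    ``exvivo`` is the plain tube used for calibration; ``s10``/``s30``/``s50``
    carry an annular plaque with 10/30/50 % diameter stenosis at the throat.
    """
    if preset not in FIXTURE_RATES:
        raise ValidationError(
            f"unknown preset {preset!r}; choose from {sorted(FIXTURE_RATES)}"
        )
    return build_geometry(FIXTURE_RATES[preset], dims)


def gen_measurements(
    gamma_true: float,
    geom_or_mesh,
    times=(60.0, 120.0),
    noise: MeasurementNoiseModel | None = None,
    spacing: float = 5e-5,
    dt: float = 1.0,
    params: TransportParams | None = None,
) -> list[AbsorptionMeasurement]:
    """Forward-model absorption percentages with multiplicative noise.

    Accepts either a geometry (meshed at ``spacing``) or a ready mesh.
    Reproducible for a fixed noise seed; ``cv = 0`` returns the exact
    forward-model values.
    """
    if gamma_true <= 0:
        raise DomainError("gamma_true must be positive")
    if noise is None:
        noise = MeasurementNoiseModel()
    if params is None:
        params = TransportParams()
    mesh = (
        geom_or_mesh
        if isinstance(geom_or_mesh, AxiMesh)
        else mesh_geometry(geom_or_mesh, spacing)
    )
    times = sorted(float(t) for t in times)
    clean = simulate_absorption(mesh, params.with_gamma(gamma_true), times, dt=dt)
    noisy = np.clip(clean * noise.factors(len(times)), 0.0, 100.0)
    return [
        AbsorptionMeasurement(dilation_time=t, absorbed_percent=float(p))
        for t, p in zip(times, noisy)
    ]
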