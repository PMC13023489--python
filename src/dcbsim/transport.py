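"""Transient axisymmetric diffusion: operator assembly and implicit stepping.

The semi-discrete system is the standard cell-centred finite-volume
discretisation of ``d(phi)/dt = div(D grad phi)`` on the (r, z) grid, with
face transmissibilities ``T_f = A_f * D_f / d`` (``A_f`` the axisymmetric
face area, ``d`` the centre-to-centre distance).  Faces between unlike
regions take the harmonic mean of the two region diffusivities unless an
explicit pair override is given; faces to void cells and all exterior faces
are zero-flux, which makes the closed system exactly conservative
(``sum_i V_i * dphi_i/dt = 0``) and the matrix an M-matrix, so backward
Euler preserves non-negativity for any step size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import NumericalError, ValidationError
from .mesh import REGION_CODES, REGION_NAMES, VOID, AxiMesh, _codes_of

__all__ = [
    "ConcentrationField",
    "DiffusivityMap",
    "BoundarySpec",
    "DiffusionOperator",
    "assemble_operator",
    "advance",
    "region_mass",
    "total_mass",
]


@dataclass
class ConcentrationField:
    """Per-cell drug concentration phi (kg/m^3) on the full mesh grid."""

    mesh: AxiMesh
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mesh.nr, self.mesh.nz):
            raise ValidationError(
                f"field shape {self.values.shape} does not match mesh grid "
                f"({self.mesh.nr}, {self.mesh.nz})"
            )

    @classmethod
    def zeros(cls, mesh: AxiMesh) -> "ConcentrationField":
        return cls(mesh, np.zeros((mesh.nr, mesh.nz)))

    @classmethod
    def uniform_in_region(
        cls, mesh: AxiMesh, regions, value: float
    ) -> "ConcentrationField":
        vals = np.zeros((mesh.nr, mesh.nz))
        vals[mesh.region_mask(regions)] = value
        return cls(mesh, vals)

    def copy(self) -> "ConcentrationField":
        return ConcentrationField(self.mesh, self.values.copy())


@dataclass(frozen=True)
class DiffusivityMap:
    """Piecewise-constant diffusivities (m^2/s) per region, with optional
    per-interface overrides.

    ``region_values`` gives the bulk diffusivity of each active region;
    ``pair_overrides`` maps an unordered region-name pair to the face
    diffusivity used on that interface (e.g. the balloon-tissue transfer
    coefficient during inflation).
    """

    region_values: dict
    pair_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, val in self.region_values.items():
            if name not in REGION_CODES or name == "void":
                raise ValidationError(f"unknown region {name!r} in diffusivity map")
            if not np.isfinite(val) or val <= 0:
                raise ValidationError(f"diffusivity for {name!r} must be > 0, got {val!r}")
        for pair, val in self.pair_overrides.items():
            if not np.isfinite(val) or val <= 0:
                raise ValidationError(f"override for {pair!r} must be > 0, got {val!r}")

    def face_value(self, region_a: str, region_b: str) -> float:
        key = frozenset({region_a, region_b})
        if key in self.pair_overrides:
            return float(self.pair_overrides[key])
        da = self.region_values.get(region_a)
        db = self.region_values.get(region_b)
        if da is None or db is None:
            raise ValidationError(
                f"diffusivity map does not cover pair ({region_a!r}, {region_b!r})"
            )
        return 2.0 * da * db / (da + db)  # harmonic mean


@dataclass(frozen=True)
class BoundarySpec:
    """Boundary conditions per named exterior surface.

    Every exterior surface of the active domain is zero-flux unless listed
    in ``scheduled_loss``, which names surfaces whose outflux is prescribed
    by a mass-loss controller (see :mod:`dcbsim.retention`); the controller,
    not a flux law, enforces the schedule.
    """

    scheduled_loss: frozenset = frozenset()

    def kind(self, surface: str) -> str:
        return "prescribed_outflux" if surface in self.scheduled_loss else "zero_flux"


ZERO_FLUX_EVERYWHERE = BoundarySpec()


class DiffusionOperator:
    """Sparse FV diffusion operator restricted to a set of active regions.

    ``matrix`` maps active-cell concentrations to their time derivative
    (units 1/s); backward-Euler factorisations are cached per step size.
    """

    def __init__(self, mesh: AxiMesh, matrix: sp.csr_matrix, active_flat: np.ndarray):
        self.mesh = mesh
        self.matrix = matrix
        self.active_flat = active_flat  # flat indices into the full grid
        self.volumes = mesh.volumes.ravel()[active_flat]
        self._lu_cache: dict[float, spla.SuperLU] = {}

    @property
    def n_active(self) -> int:
        return len(self.active_flat)

    def solver(self, dt: float):
        key = float(dt)
        lu = self._lu_cache.get(key)
        if lu is None:
            n = self.n_active
            A = (sp.identity(n, format="csc") - dt * self.matrix.tocsc()).tocsc()
            try:
                lu = spla.splu(A)
            except RuntimeError as exc:  # pragma: no cover - singular systems
                raise NumericalError(f"backward-Euler factorisation failed: {exc}") from exc
            self._lu_cache[key] = lu
        return lu


def assemble_operator(
    mesh: AxiMesh, dmap: DiffusivityMap, regions=None
) -> DiffusionOperator:
    """Assemble the axisymmetric FV diffusion operator.

    Parameters
    ----------
    regions:
        Region names forming the active domain; defaults to every region the
        diffusivity map covers.  Faces to regions outside the active set are
        zero-flux (used to drop the balloon domain during retention).
    """
    if regions is None:
        regions = set(dmap.region_values)
    codes = _codes_of(regions)
    codes.discard(VOID)
    for c in codes:
        if REGION_NAMES[c] not in dmap.region_values:
            raise ValidationError(f"no diffusivity given for region {REGION_NAMES[c]!r}")

    lab = mesh.labels
    nr, nz = mesh.nr, mesh.nz
    active = np.isin(lab, list(codes))
    flat_index = -np.ones((nr, nz), dtype=np.int64)
    active_flat = np.flatnonzero(active.ravel())
    flat_index.ravel()[active_flat] = np.arange(len(active_flat))

    # 4x4 face-diffusivity lookup by label-code pair
    lut = np.zeros((4, 4))
    code_list = sorted(codes)
    for a in code_list:
        for b in code_list:
            lut[a, b] = dmap.face_value(REGION_NAMES[a], REGION_NAMES[b])

    dr = np.diff(mesh.r_edges)
    dz = np.diff(mesh.z_edges)
    rbar = mesh.r_centers
    vol = mesh.volumes

    rows, cols, data = [], [], []

    def add_faces(mask, ca, cb, trans):
        ia = flat_index.ravel()[ca[mask]]
        ib = flat_index.ravel()[cb[mask]]
        t = trans[mask]
        va = vol.ravel()[ca[mask]]
        vb = vol.ravel()[cb[mask]]
        rows.extend([ia, ib, ia, ib])
        cols.extend([ib, ia, ia, ib])
        data.extend([t / va, t / vb, -t / va, -t / vb])

    flat = np.arange(nr * nz).reshape(nr, nz)

    # radial faces
    la, lb = lab[:-1, :], lab[1:, :]
    both = np.isin(la, list(codes)) & np.isin(lb, list(codes))
    if both.any():
        area = 2.0 * np.pi * mesh.r_edges[1:-1][:, None] * dz[None, :]
        dist = (0.5 * (dr[:-1] + dr[1:]))[:, None] * np.ones((1, nz))
        trans = area * lut[la, lb] / dist
        add_faces(both, flat[:-1, :], flat[1:, :], trans)

    # axial faces
    lc, ld = lab[:, :-1], lab[:, 1:]
    both = np.isin(lc, list(codes)) & np.isin(ld, list(codes))
    if both.any():
        area = (2.0 * np.pi * rbar * dr)[:, None] * np.ones((1, nz - 1))
        dist = np.ones((nr, 1)) * (0.5 * (dz[:-1] + dz[1:]))[None, :]
        trans = area * lut[lc, ld] / dist
        add_faces(both, flat[:, :-1], flat[:, 1:], trans)

    n = len(active_flat)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.concatenate(data)
        matrix = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    else:
        matrix = sp.csr_matrix((n, n))
    return DiffusionOperator(mesh, matrix, active_flat)


def advance(
    field: ConcentrationField,
    op: DiffusionOperator,
    dt: float,
    bcs: BoundarySpec = ZERO_FLUX_EVERYWHERE,
) -> ConcentrationField:
    """One backward-Euler step of length ``dt`` seconds.

    Exterior faces are zero-flux (``bcs`` surfaces with prescribed outflux
    are handled by the retention controller, not here), so the step is
    exactly mass-conserving up to solver round-off, unconditionally stable,
    and positivity-preserving.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    x = field.values.ravel()[op.active_flat]
    y = op.solver(dt).solve(x)
    y = np.maximum(y, 0.0)  # clip direct-solver round-off
    out = field.values.copy()
    out.ravel()[op.active_flat] = y
    return ConcentrationField(field.mesh, out)


def region_mass(field: ConcentrationField, mesh: AxiMesh, regions) -> float:
    """Total drug mass (kg) held in the named region(s): sum of phi_c * V_c."""
    mask = mesh.region_mask(regions)
    return float((field.values[mask] * mesh.volumes[mask]).sum())


def total_mass(field: ConcentrationField, mesh: AxiMesh) -> float:
    """Drug mass (kg) over all non-void regions."""
    return region_mass(field, mesh, mesh.region_names_present())
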