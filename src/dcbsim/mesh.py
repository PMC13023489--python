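"""Structured axisymmetric (r, z) meshes with region labels.

The mesh is a global rectilinear grid in the (r, z) half-plane.  Every cell
carries exactly one region label -- balloon, plaque, wall, or void -- chosen
by testing the cell centre against the continuous geometry (a standard
staircase representation of the curved plaque/balloon interfaces).  Cell
volumes are the exact annular volumes 2*pi*r_bar*dr*dz, so summed region
volumes of grid-aligned annuli (e.g. the wall) telescope to the closed-form
value.

Named surfaces follow the solver conventions of the transport stages:

* interior interfaces: ``plaque-balloon``, ``vessel-balloon``,
  ``vessel-plaque`` (faces between cells of the two named regions);
* exterior surfaces: ``vessel`` (outer wall), ``vessel-in`` / ``vessel-out``
  (axial ends), ``balloon`` (balloon surface not facing tissue), ``lumen``
  (tissue surface exposed to the lumen outside the balloon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ResolutionError, ValidationError
from .geometry import StenosisGeometry

__all__ = [
    "VOID",
    "BALLOON",
    "PLAQUE",
    "WALL",
    "REGION_CODES",
    "REGION_NAMES",
    "TISSUE_REGIONS",
    "AxiMesh",
    "mesh_geometry",
]

VOID, BALLOON, PLAQUE, WALL = 0, 1, 2, 3
REGION_CODES = {"void": VOID, "balloon": BALLOON, "plaque": PLAQUE, "wall": WALL}
REGION_NAMES = {code: name for name, code in REGION_CODES.items()}
TISSUE_REGIONS = frozenset({"plaque", "wall"})

# interior interface names keyed by the unordered label pair
_INTERFACE_OF_PAIR = {
    frozenset({BALLOON, PLAQUE}): "plaque-balloon",
    frozenset({BALLOON, WALL}): "vessel-balloon",
    frozenset({PLAQUE, WALL}): "vessel-plaque",
}

_EPS = 1e-12


@dataclass
class FaceList:
    """Faces of one named interior interface.

    ``cells_a``/``cells_b`` are flat indices into the full (nr*nz) grid of
    the two cells sharing each face; ``areas`` are the face areas (m^2).
    For interfaces involving the balloon, ``cells_b`` is always the balloon
    side.
    """

    cells_a: np.ndarray
    cells_b: np.ndarray
    areas: np.ndarray

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass
class BoundaryList:
    """Exterior faces of one named surface: owning cells plus face areas."""

    cells: np.ndarray
    areas: np.ndarray

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass
class AxiMesh:
    """Structured axisymmetric cell grid with region labels.

    Attributes
    ----------
    r_edges, z_edges:
        Cell-edge coordinates (monotone increasing, metres).
    labels:
        Integer region code per cell, shape ``(nr, nz)``.
    volumes:
        Axisymmetric cell volumes ``2*pi*r_bar*dr*dz``, shape ``(nr, nz)``.
    interfaces, boundaries:
        Named interior interfaces / exterior surfaces (see module docstring).
    """

    r_edges: np.ndarray
    z_edges: np.ndarray
    labels: np.ndarray
    geometry: StenosisGeometry | None = None
    interfaces: dict[str, FaceList] = field(default_factory=dict)
    boundaries: dict[str, BoundaryList] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r_edges = np.asarray(self.r_edges, dtype=float)
        self.z_edges = np.asarray(self.z_edges, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if np.any(np.diff(self.r_edges) <= 0) or np.any(np.diff(self.z_edges) <= 0):
            raise ValidationError("mesh edge coordinates must be strictly increasing")
        if self.labels.shape != (self.nr, self.nz):
            raise ValidationError(
                f"labels shape {self.labels.shape} does not match grid "
                f"({self.nr}, {self.nz})"
            )
        dr = np.diff(self.r_edges)
        dz = np.diff(self.z_edges)
        rbar = 0.5 * (self.r_edges[:-1] + self.r_edges[1:])
        self.volumes = 2.0 * np.pi * rbar[:, None] * dr[:, None] * dz[None, :]
        if np.any(self.volumes <= 0):
            raise ValidationError("all cell volumes must be positive")
        if not self.interfaces and not self.boundaries:
            self._build_surfaces()

    # -- basic grid queries ------------------------------------------------
    @property
    def nr(self) -> int:
        return len(self.r_edges) - 1

    @property
    def nz(self) -> int:
        return len(self.z_edges) - 1

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def n_cells(self) -> int:
        return self.nr * self.nz

    def region_mask(self, regions) -> np.ndarray:
        codes = _codes_of(regions)
        return np.isin(self.labels, list(codes))

    def region_volume(self, regions) -> float:
        """Total meshed volume (m^3) of the named region(s)."""
        return float(self.volumes[self.region_mask(regions)].sum())

    def region_names_present(self) -> set[str]:
        return {REGION_NAMES[c] for c in np.unique(self.labels) if c != VOID}

    # -- surface bookkeeping -----------------------------------------------
    def _build_surfaces(self) -> None:
        nr, nz = self.nr, self.nz
        lab = self.labels
        dr = np.diff(self.r_edges)
        dz = np.diff(self.z_edges)
        rbar = self.r_centers
        flat = np.arange(nr * nz).reshape(nr, nz)

        iface: dict[str, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
        bnd: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}

        def add_iface(name, a, b, areas):
            iface.setdefault(name, []).append((a, b, areas))

        def add_bnd(name, cells, areas):
            bnd.setdefault(name, []).append((cells, areas))

        # radial faces between cells (i, j) and (i+1, j)
        la, lb = lab[:-1, :], lab[1:, :]
        r_int = self.r_edges[1:-1]  # interior radial edges
        area_rad = 2.0 * np.pi * r_int[:, None] * dz[None, :]
        # axial faces between cells (i, j) and (i, j+1)
        area_ax = (2.0 * np.pi * rbar * dr)[:, None] * np.ones((1, nz - 1))
        lc, ld = lab[:, :-1], lab[:, 1:]

        for pair, name in _INTERFACE_OF_PAIR.items():
            p0, p1 = sorted(pair)
            b_side = BALLOON if BALLOON in pair else p1
            for (lx, ly, cx, cy, areas) in (
                (la, lb, flat[:-1, :], flat[1:, :], area_rad),
                (lc, ld, flat[:, :-1], flat[:, 1:], area_ax),
            ):
                m = ((lx == p0) & (ly == p1)) | ((lx == p1) & (ly == p0))
                if not m.any():
                    continue
                # orient: cells_b holds the b_side (balloon) cells
                swap = ly[m] != b_side
                a, b = np.where(swap, cy[m], cx[m]), np.where(swap, cx[m], cy[m])
                add_iface(name, a, b, areas[m])

        active = lab != VOID
        # exterior surfaces in the radial direction; cell has void/outside above it:
        above_void = np.ones_like(active)
        above_void[:-1, :] = ~active[1:, :]
        below_void = np.ones_like(active)
        below_void[1:, :] = ~active[:-1, :]
        r_up = self.r_edges[1:]
        r_dn = self.r_edges[:-1]
        for mask, redge, outward in (
            (active & above_void, r_up, "up"),
            (active & below_void, r_dn, "down"),
        ):
            if not mask.any():
                continue
            ii, jj = np.nonzero(mask)
            areas = 2.0 * np.pi * redge[ii] * dz[jj]
            labs = lab[ii, jj]
            cells = flat[ii, jj]
            is_wall_outer = (labs == WALL) & (outward == "up")
            is_balloon = labs == BALLOON
            is_lumen = ~is_wall_outer & ~is_balloon
            if is_wall_outer.any():
                add_bnd("vessel", cells[is_wall_outer], areas[is_wall_outer])
            if is_balloon.any():
                add_bnd("balloon", cells[is_balloon], areas[is_balloon])
            if is_lumen.any():
                add_bnd("lumen", cells[is_lumen], areas[is_lumen])
        # axial ends
        for j, name in ((0, "vessel-in"), (nz - 1, "vessel-out")):
            col = active[:, j]
            if col.any():
                ii = np.nonzero(col)[0]
                areas = 2.0 * np.pi * rbar[ii] * dr[ii]
                labs = lab[ii, j]
                cells = flat[ii, j]
                tis = labs != BALLOON
                if tis.any():
                    add_bnd(name, cells[tis], areas[tis])
                if (~tis).any():
                    add_bnd("balloon", cells[~tis], areas[~tis])
        # axial faces where an active cell meets void (balloon/plaque ends)
        for lx, ly, cx, cy in ((lc, ld, flat[:, :-1], flat[:, 1:]),):
            m_av = (lx != VOID) & (ly == VOID)
            m_va = (lx == VOID) & (ly != VOID)
            for m, cown, lown in ((m_av, cx, lx), (m_va, cy, ly)):
                if not m.any():
                    continue
                cells = cown[m]
                labs = lown[m]
                areas = area_ax[m]
                isb = labs == BALLOON
                if isb.any():
                    add_bnd("balloon", cells[isb], areas[isb])
                if (~isb).any():
                    add_bnd("lumen", cells[~isb], areas[~isb])

        self.interfaces = {
            name: FaceList(
                cells_a=np.concatenate([a for a, _, _ in parts]),
                cells_b=np.concatenate([b for _, b, _ in parts]),
                areas=np.concatenate([s for _, _, s in parts]),
            )
            for name, parts in iface.items()
        }
        self.boundaries = {
            name: BoundaryList(
                cells=np.concatenate([c for c, _ in parts]),
                areas=np.concatenate([s for _, s in parts]),
            )
            for name, parts in bnd.items()
        }

    def loss_surface_cells(self) -> np.ndarray:
        """Tissue cells on the former plaque-balloon contact surface.

        These are the cells from which the prescribed post-withdrawal mass
        loss is taken.  On a plain tube (no plaque) the contact surface is
        the vessel-balloon interface instead.
        """
        for name in ("plaque-balloon", "vessel-balloon"):
            if name in self.interfaces:
                return np.unique(self.interfaces[name].cells_a)
        raise ValidationError("mesh has no balloon contact interface")


def _codes_of(regions) -> set[int]:
    if isinstance(regions, str):
        regions = {regions}
    codes = set()
    for name in regions:
        if name not in REGION_CODES:
            raise ValidationError(f"unknown region label {name!r}")
        codes.add(REGION_CODES[name])
    return codes


def mesh_geometry(geom: StenosisGeometry, target_spacing: float) -> AxiMesh:
    """Discretise a geometry into a structured axisymmetric mesh.

    The radial grid is anchored at multiples of ``target_spacing`` from the
    axis so that grid-aligned interfaces (lumen and outer wall radius for the
    default dimensions) are meshed exactly.  The axial spacing is adjusted to
    divide the vessel length evenly.

    Raises
    ------
    ResolutionError
        If the spacing cannot place at least two cells across the thinnest
        region it must resolve (offending region named in the message).
    """
    h = float(target_spacing)
    if h <= 0:
        raise ValidationError("target_spacing must be positive")
    dims = geom.dims
    if h > dims.balloon_thickness / 2.0 + _EPS:
        raise ResolutionError(
            f"spacing {h:g} m too coarse for region 'balloon' "
            f"(shell thickness {dims.balloon_thickness:g} m needs >= 2 cells)"
        )
    if h > dims.wall_thickness / 2.0 + _EPS:
        raise ResolutionError(
            f"spacing {h:g} m too coarse for region 'wall' "
            f"(thickness {dims.wall_thickness:g} m needs >= 2 cells)"
        )
    if geom.has_plaque:
        throat_thick = geom.stenosis_rate * dims.lumen_radius
        if h > throat_thick / 2.0 + _EPS:
            raise ResolutionError(
                f"spacing {h:g} m too coarse for region 'plaque' "
                f"(throat thickness {throat_thick:g} m needs >= 2 cells)"
            )

    r_out = dims.outer_radius
    r_in = geom.throat_radius - dims.balloon_thickness
    i_lo = int(np.floor(r_in / h + _EPS))
    i_hi = int(np.ceil(r_out / h - _EPS))
    r_edges = h * np.arange(i_lo, i_hi + 1)

    nz = max(1, int(round(dims.vessel_length / h)))
    z_edges = np.linspace(0.0, dims.vessel_length, nz + 1)

    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])

    r_plq = geom.plaque_inner_radius(zc)
    contact = geom.contact_radius(zc)
    b_lo, b_hi = geom.balloon_span
    in_balloon_span = (zc >= b_lo - _EPS) & (zc <= b_hi + _EPS)
    balloon_inner = contact - dims.balloon_thickness

    R = rc[:, None]
    is_wall = (R > dims.lumen_radius) & (R < r_out)
    is_plaque = (R > r_plq[None, :]) & (R < dims.lumen_radius)
    is_balloon = (
        in_balloon_span[None, :]
        & (R > balloon_inner[None, :])
        & (R < contact[None, :])
    )
    labels = np.select(
        [is_balloon, is_plaque, is_wall], [BALLOON, PLAQUE, WALL], default=VOID
    ).astype(np.int8)

    return AxiMesh(r_edges=r_edges, z_edges=z_edges, labels=labels, geometry=geom)
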