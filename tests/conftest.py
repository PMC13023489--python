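"""Shared fixtures: compact geometries sized for fast, well-resolved tests."""

import numpy as np
import pytest

from dcbsim import (
    TransportParams,
    VesselDims,
    build_geometry,
    mesh_geometry,
)
from dcbsim.mesh import AxiMesh, BALLOON, WALL


@pytest.fixture(scope="session")
def small_dims():
    """Short vessel segment: keeps transfer/retention runs to ~1k cells."""
    return VesselDims(
        lumen_radius=1.5e-3,
        wall_thickness=0.5e-3,
        vessel_length=4.0e-3,
        plaque_half_length=1.0e-3,
        balloon_thickness=0.1e-3,
        balloon_length=2.0e-3,
    )


@pytest.fixture(scope="session")
def params():
    return TransportParams()


@pytest.fixture(scope="session")
def mesh_small_exvivo(small_dims):
    return mesh_geometry(build_geometry(0.0, small_dims), 5e-5)


@pytest.fixture(scope="session")
def mesh_small_s50(small_dims):
    return mesh_geometry(build_geometry(0.5, small_dims), 5e-5)


def make_slab_mesh(spacing, balloon_thickness=1e-4, wall_thickness=2e-4,
                   base_radius=0.1, z_depth=1e-3):
    """Quasi-planar two-slab mesh: balloon slab against a tissue slab.

    One axial column at a large base radius, so curvature is negligible and
    radial diffusion matches the planar two-media problem.
    """
    n_b = int(round(balloon_thickness / spacing))
    n_w = int(round(wall_thickness / spacing))
    n = n_b + n_w
    r_edges = base_radius + spacing * np.arange(n + 1)
    z_edges = np.array([0.0, z_depth])
    labels = np.full((n, 1), WALL, dtype=np.int8)
    labels[:n_b, 0] = BALLOON
    return AxiMesh(r_edges=r_edges, z_edges=z_edges, labels=labels)


@pytest.fixture(scope="session")
def slab_mesh():
    return make_slab_mesh(2e-6)
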