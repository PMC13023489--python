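"""Geometry construction and axisymmetric meshing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcbsim import VesselDims, build_geometry, mesh_geometry
from dcbsim.errors import DomainError, ResolutionError, ValidationError
from dcbsim.mesh import VOID


class TestBuildGeometry:
    def test_zero_stenosis_is_plain_tube(self):
        geom = build_geometry(0.0)
        z = np.linspace(0, geom.dims.vessel_length, 50)
        assert not geom.has_plaque
        assert np.allclose(geom.plaque_inner_radius(z), geom.dims.lumen_radius)

    def test_throat_radius_follows_diameter_reduction(self):
        geom = build_geometry(0.5, VesselDims(lumen_radius=1.5e-3))
        assert geom.throat_radius == pytest.approx(0.75e-3)
        # the continuous profile reaches the throat value at mid-vessel
        assert geom.plaque_inner_radius(geom.z_mid) == pytest.approx(0.75e-3)

    @pytest.mark.parametrize("rate", [-0.1, 1.0, 1.2])
    def test_invalid_stenosis_rate(self, rate):
        with pytest.raises(DomainError):
            build_geometry(rate)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValidationError):
            VesselDims(lumen_radius=-1e-3)
        with pytest.raises(ValidationError):
            VesselDims(wall_thickness=0.0)

    def test_balloon_longer_than_vessel_rejected(self):
        with pytest.raises(ValidationError):
            VesselDims(balloon_length=25e-3)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(rate=st.floats(0.01, 0.95))
    def test_plaque_profile_invariants(self, rate):
        geom = build_geometry(rate)
        z = np.linspace(0, geom.dims.vessel_length, 301)
        r_p = geom.plaque_inner_radius(z)
        assert np.all(r_p <= geom.dims.lumen_radius + 1e-15)
        assert np.min(r_p) == pytest.approx(geom.dims.lumen_radius * (1 - rate))
        # shoulders taper smoothly to zero thickness
        z0, z1 = geom.plaque_span
        assert geom.plaque_thickness(z0) == pytest.approx(0.0, abs=1e-12)
        assert geom.plaque_thickness(z1) == pytest.approx(0.0, abs=1e-12)


class TestMeshGeometry:
    def test_wall_volume_matches_closed_form_annulus(self):
        geom = build_geometry(0.0)
        mesh = mesh_geometry(geom, 5e-5)
        d = geom.dims
        exact = np.pi * (d.outer_radius**2 - d.lumen_radius**2) * d.vessel_length
        assert mesh.region_volume("wall") == pytest.approx(exact, rel=0.01)

    def test_labels_partition_and_volumes_positive(self, mesh_small_s50):
        mesh = mesh_small_s50
        assert np.all(mesh.volumes > 0)
        # every non-void cell carries exactly one known region label
        assert set(np.unique(mesh.labels)) <= {0, 1, 2, 3}
        assert mesh.region_names_present() == {"balloon", "plaque", "wall"}

    def test_spacing_too_coarse_names_offending_region(self):
        with pytest.raises(ResolutionError, match="balloon"):
            mesh_geometry(build_geometry(0.0), 2e-4)
        # a plaque thinner than the balloon shell binds first
        with pytest.raises(ResolutionError, match="plaque"):
            mesh_geometry(build_geometry(0.05), 4e-5)

    @pytest.mark.parametrize("rate", [0.0, 0.1, 0.5])
    def test_refinement_changes_region_volumes_below_half_percent(self, rate):
        geom = build_geometry(rate)
        coarse = mesh_geometry(geom, 5e-5)
        fine = mesh_geometry(geom, 2.5e-5)
        for region in coarse.region_names_present():
            v1, v2 = coarse.region_volume(region), fine.region_volume(region)
            assert abs(v2 - v1) / v1 < 0.005, region

    def test_named_surfaces_present(self, mesh_small_s50):
        assert {"plaque-balloon", "vessel-balloon", "vessel-plaque"} <= set(
            mesh_small_s50.interfaces
        )
        assert {"vessel", "vessel-in", "vessel-out", "balloon"} <= set(
            mesh_small_s50.boundaries
        )

    # a thin plaque (s10) needs finer spacing before its tapered shoulders
    # are labelled as plaque rather than wall
    @pytest.mark.parametrize("rate,h", [(0.1, 2.5e-5), (0.3, 5e-5), (0.5, 5e-5)])
    def test_plaque_balloon_contact_exceeds_vessel_balloon(self, rate, h):
        mesh = mesh_geometry(build_geometry(rate), h)
        assert (
            mesh.interfaces["plaque-balloon"].total_area
            > mesh.interfaces["vessel-balloon"].total_area
        )

    def test_balloon_spans_at_least_two_cells_radially(self, mesh_small_exvivo):
        labels = mesh_small_exvivo.labels
        cols_with_balloon = np.flatnonzero((labels == 1).any(axis=0))
        counts = (labels[:, cols_with_balloon] == 1).sum(axis=0)
        assert counts.min() >= 2

    def test_void_outside_active_domain(self, mesh_small_exvivo):
        # beyond the balloon span the lumen band must be void
        mesh = mesh_small_exvivo
        assert (mesh.labels[:, 0] != VOID).sum() > 0
        inner = mesh.labels[0, 0]  # innermost radius at inlet, outside balloon
        assert inner == VOID
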