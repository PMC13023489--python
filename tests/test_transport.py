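"""Finite-volume diffusion operator: conservation, stability, analytic checks."""

import numpy as np
import pytest
import scipy.linalg
import scipy.special

from dcbsim import (
    ConcentrationField,
    DiffusivityMap,
    TransportParams,
    advance,
    assemble_operator,
    region_mass,
    run_transfer,
    total_mass,
)
from dcbsim.errors import ValidationError
from conftest import make_slab_mesh


def uniform_dmap(value=1e-12):
    return DiffusivityMap(
        region_values={"balloon": value, "plaque": value, "wall": value}
    )


class TestOperator:
    def test_interior_row_sums_vanish(self, mesh_small_s50):
        op = assemble_operator(mesh_small_s50, uniform_dmap())
        rows = np.asarray(op.matrix.sum(axis=1)).ravel()
        scale = np.abs(op.matrix.diagonal()).max()
        assert np.abs(rows).max() < 1e-12 * scale

    def test_constant_field_in_null_space(self, mesh_small_s50):
        op = assemble_operator(mesh_small_s50, uniform_dmap())
        ones = np.ones(op.n_active)
        scale = np.abs(op.matrix.diagonal()).max()
        assert np.abs(op.matrix @ ones).max() < 1e-12 * scale

    def test_negative_diffusivity_rejected(self):
        with pytest.raises(ValidationError):
            DiffusivityMap(region_values={"wall": -1e-12})

    def test_1d_operator_eigenvalues_nonpositive(self):
        mesh = make_slab_mesh(1e-5, balloon_thickness=1e-4, wall_thickness=3e-4)
        op = assemble_operator(mesh, uniform_dmap())
        assert op.n_active <= 50
        lam = np.linalg.eigvals(op.matrix.toarray())
        assert lam.real.max() < 1e-12 * np.abs(lam.real).max()


class TestAdvance:
    def test_uniform_field_is_steady_state(self, mesh_small_s50):
        op = assemble_operator(mesh_small_s50, uniform_dmap())
        fld = ConcentrationField.uniform_in_region(
            mesh_small_s50, {"balloon", "plaque", "wall"}, 3.0
        )
        out = advance(fld, op, 1e4)
        mask = mesh_small_s50.region_mask({"balloon", "plaque", "wall"})
        assert np.allclose(out.values[mask], 3.0, rtol=1e-12)

    def test_mass_conserved_under_zero_flux(self, mesh_small_s50, params):
        op = assemble_operator(mesh_small_s50, uniform_dmap(params.gamma_transfer))
        fld = ConcentrationField.uniform_in_region(
            mesh_small_s50, "balloon", params.c0_balloon
        )
        m0 = total_mass(fld, mesh_small_s50)
        for _ in range(10):
            fld = advance(fld, op, 5.0)
        assert total_mass(fld, mesh_small_s50) == pytest.approx(m0, rel=1e-10)

    @pytest.mark.parametrize("dt", [1.0, 1e2, 1e4, 1e6])
    def test_unconditional_stability_and_positivity(self, mesh_small_s50, dt):
        op = assemble_operator(mesh_small_s50, uniform_dmap())
        fld = ConcentrationField.uniform_in_region(mesh_small_s50, "balloon", 75.32)
        out = advance(advance(fld, op, dt), op, dt)
        assert np.all(np.isfinite(out.values))
        assert np.all(out.values >= 0.0)
        assert out.values.max() <= 75.32 * (1 + 1e-9)

    def test_matches_matrix_exponential_oracle(self):
        """Backward Euler vs dense expm of the same semi-discrete system."""
        mesh = make_slab_mesh(1e-5, balloon_thickness=1e-4, wall_thickness=3e-4)
        op = assemble_operator(mesh, uniform_dmap())
        assert op.n_active <= 50
        r = mesh.r_centers
        x0 = 1.0 + 0.5 * np.cos(np.pi * (r - r[0]) / (r[-1] - r[0]))
        dt, n = 200.0, 10
        fld = ConcentrationField(mesh, x0[:, None].copy())
        for _ in range(n):
            fld = advance(fld, op, dt)
        num = fld.values.ravel()[op.active_flat]
        exact = scipy.linalg.expm(op.matrix.toarray() * dt * n) @ x0
        assert np.linalg.norm(num - exact) / np.linalg.norm(exact) < 1e-3

    def test_two_slab_profile_matches_erfc_solution(self, slab_mesh):
        """Contact of a loaded slab with a clean slab of equal diffusivity.

        The interface-adjacent profile must match the classical
        complementary-error-function solution of the two-media problem.
        """
        D, c0, t_end = 1e-12, 75.32, 60.0
        params = TransportParams(gamma_transfer=D, c0_balloon=c0)
        res = run_transfer(slab_mesh, params, t_end, dt=0.25)
        x = slab_mesh.r_centers - (slab_mesh.r_edges[0] + 1e-4)  # 0 at interface
        width = np.sqrt(4 * D * t_end)
        analytic = 0.5 * c0 * scipy.special.erfc(x / width)
        sel = np.abs(x) <= width  # interface-adjacent band
        num = res.field.values[:, 0]
        err = np.abs(num[sel] - analytic[sel]) / (0.5 * c0)
        assert err.max() < 0.02

    def test_grid_convergence_of_absorbed_mass(self):
        """Absorbed mass changes < 1 % when the spacing is halved."""
        params = TransportParams()
        absorbed = []
        for h in (2.5e-6, 1.25e-6):
            mesh = make_slab_mesh(h)
            res = run_transfer(mesh, params, 60.0, dt=1.0)
            absorbed.append(region_mass(res.field, mesh, "wall"))
        assert abs(absorbed[1] - absorbed[0]) / absorbed[1] < 0.01


class TestRegionMass:
    def test_zero_field_zero_mass(self, mesh_small_s50):
        fld = ConcentrationField.zeros(mesh_small_s50)
        assert region_mass(fld, mesh_small_s50, {"plaque", "wall"}) == 0.0

    def test_uniform_balloon_mass_is_concentration_times_volume(self, mesh_small_s50):
        fld = ConcentrationField.uniform_in_region(mesh_small_s50, "balloon", 75.32)
        expected = 75.32 * mesh_small_s50.region_volume("balloon")
        assert region_mass(fld, mesh_small_s50, "balloon") == pytest.approx(expected)

    def test_additivity_over_regions(self, mesh_small_s50):
        rng = np.random.default_rng(0)
        fld = ConcentrationField(
            mesh_small_s50, rng.random((mesh_small_s50.nr, mesh_small_s50.nz))
        )
        total = region_mass(fld, mesh_small_s50, {"balloon", "plaque", "wall"})
        parts = sum(
            region_mass(fld, mesh_small_s50, r) for r in ("balloon", "plaque", "wall")
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_unknown_region_rejected(self, mesh_small_s50):
        fld = ConcentrationField.zeros(mesh_small_s50)
        with pytest.raises(ValidationError):
            region_mass(fld, mesh_small_s50, {"lumen_jelly"})
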