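"""Finite-element solver verification: closed forms, patch test, physics."""

import math

import numpy as np
import pytest

from epimech import fem, stress
from epimech.fem import (
    BoundaryConditions,
    DirichletBC,
    IncompressibilityError,
    LoadCase,
    Material,
    MaterialMap,
    SolverOptions,
    UniformPressure,
    assemble_and_solve,
    default_materials,
    lame_parameters,
    sector_pressure,
)
from epimech.geometry import SubdomainLabel, VariantId
from epimech.synthetic import rectangle_mesh


class TestLameParameters:
    @pytest.mark.parametrize(
        "E,nu,lam,mu",
        [
            (1.0, 0.0, 0.0, 0.5),
            (6.0, 0.47, 6 * 0.47 / (1.47 * 0.06), 6 / (2 * 1.47)),  # cartilage
            (500.0, 0.20, 500 * 0.2 / (1.2 * 0.6), 500 / 2.4),  # dense bone
        ],
    )
    def test_values(self, E, nu, lam, mu):
        l, m = lame_parameters(E, nu)
        assert l == pytest.approx(lam, rel=1e-12)
        assert m == pytest.approx(mu, rel=1e-12)

    def test_cartilage_magnitudes(self):
        l, m = lame_parameters(6.0, 0.47)
        assert l == pytest.approx(31.973, abs=5e-3)
        assert m == pytest.approx(2.0408, abs=5e-4)

    def test_incompressible_rejected(self):
        with pytest.raises(IncompressibilityError):
            lame_parameters(1.0, 0.5)


class TestSectorPressure:
    def test_profile(self):
        lc = LoadCase(peak_pressure=0.3, sector_center_angle=90.0)
        assert sector_pressure(90.0, lc) == pytest.approx(0.3)
        assert sector_pressure(90.0 + 22.5, lc) == pytest.approx(0.0)
        assert sector_pressure(90.0 - 22.5, lc) == pytest.approx(0.0)
        assert sector_pressure(90.0 + 11.25, lc) == pytest.approx(0.225)
        assert sector_pressure(150.0, lc) == 0.0  # clamped outside support

    def test_wide_support_reading(self):
        lc = LoadCase(peak_pressure=3.0, sector_center_angle=90.0, wide_support=True)
        assert sector_pressure(90.0, lc) == pytest.approx(3.0)
        assert sector_pressure(90.0 + 67.5, lc) == pytest.approx(0.0)
        assert sector_pressure(90.0 + 22.5, lc) > 0.0


class TestBlockOracle:
    def test_small_strain_matches_closed_form(self, block):
        sol = assemble_and_solve(
            block.mesh, block.materials, block.bc, block.load,
            SolverOptions(small_strain=True),
        )
        top = sol.qmesh.nodes_with_tag("top")
        u_top = sol.u[top, 1].mean()
        assert u_top == pytest.approx(block.u_top_analytic, rel=5e-3)
        assert block.u_top_analytic == pytest.approx(-0.012985, abs=1e-6)

    def test_finite_strain_close_to_linear_at_small_load(self, block):
        sol = assemble_and_solve(block.mesh, block.materials, block.bc, block.load)
        top = sol.qmesh.nodes_with_tag("top")
        assert sol.u[top, 1].mean() == pytest.approx(block.u_top_analytic, rel=5e-3)

    def test_zero_load_zero_displacement(self, block):
        sol = assemble_and_solve(
            block.mesh, block.materials, block.bc,
            UniformPressure(pressure=0.0, edge_tag="top"),
        )
        assert np.allclose(sol.u, 0.0)

    def test_patch_test_affine_field(self, block):
        """Quadratic elements reproduce an imposed affine field exactly."""
        a = np.array([[2.0, 0.5], [0.3, -1.2]]) * 1e-3

        bc = BoundaryConditions(
            dirichlet=(
                DirichletBC("__all__", 0, lambda x, y: a[0, 0] * x + a[0, 1] * y),
                DirichletBC("__all__", 1, lambda x, y: a[1, 0] * x + a[1, 1] * y),
            )
        )
        sol = assemble_and_solve(
            block.mesh, block.materials, bc, None, SolverOptions(small_strain=True)
        )
        exact = sol.qmesh.nodes @ a.T
        assert np.abs(sol.u - exact).max() < 1e-10

    def test_linearity_of_small_strain_path(self, block):
        sols = []
        for p in (0.01, 0.02):
            sols.append(
                assemble_and_solve(
                    block.mesh, block.materials, block.bc,
                    UniformPressure(pressure=p, edge_tag="top"),
                    SolverOptions(small_strain=True),
                )
            )
        assert np.allclose(2.0 * sols[0].u, sols[1].u, rtol=1e-9, atol=1e-14)


class TestEpiphysisPhysics:
    H = 2.0  # coarse test mesh

    def test_low_load_linearization(self, solve_cache):
        """At peak <= 1e-3 E_C, finite and small strain agree to 0.1%."""
        peak = 1e-3
        fin = solve_cache.run(VariantId.WITH_SOC, self.H, peak)
        lin = solve_cache.run(VariantId.WITH_SOC, self.H, peak, small_strain=True)
        assert fin["deflection"] == pytest.approx(lin["deflection"], rel=1e-3)

    def test_symmetry_under_vertical_load(self, solve_cache):
        run = solve_cache.run(VariantId.WITH_SOC, self.H, 0.3)
        sol, mesh = run["sol"], run["mesh"]
        nodes = sol.qmesh.nodes
        from scipy.spatial import cKDTree

        tree = cKDTree(nodes)
        d, j = tree.query(nodes * np.array([-1.0, 1.0]))
        assert d.max() < 1e-8  # the quadratic mesh is exactly symmetric
        mirrored = np.column_stack([-sol.u[j, 0], sol.u[j, 1]])
        err = np.linalg.norm(sol.u - mirrored)
        assert err <= 1e-6 * np.linalg.norm(sol.u)

    def test_monotonicity_small_load_doubling(self, solve_cache):
        u1 = solve_cache.run(VariantId.WITH_SOC, self.H, 1e-3)["sol"].u
        u2 = solve_cache.run(VariantId.WITH_SOC, self.H, 2e-3)["sol"].u
        assert np.linalg.norm(u2) == pytest.approx(2 * np.linalg.norm(u1), rel=5e-3)

    def test_soc_stiffens_structure(self, solve_cache):
        """Same mesh and load: the stiff insert reduces apex deflection."""
        d_with = solve_cache.run(VariantId.WITH_SOC, self.H, 0.3)["deflection"]
        d_without = solve_cache.run(VariantId.NO_SOC, self.H, 0.3)["deflection"]
        assert d_with < d_without

    def test_protrusions_stiffen_less_than_soc(self, solve_cache):
        """Ossified protrusions fall short of the SOC's stiffening under
        vertical load: apex deflection orders SOC < protrusions < none."""
        d_no = solve_cache.run(VariantId.NO_SOC, self.H, 0.3)["deflection"]
        d_pro = solve_cache.run(VariantId.PROTRUSIONS_EXTENDED, self.H, 0.3)["deflection"]
        d_soc = solve_cache.run(VariantId.WITH_SOC, self.H, 0.3)["deflection"]
        assert d_soc < d_pro < d_no

    def test_nonconvergence_reports_last_fraction(self, solve_cache):
        """Beyond the constitutive limit load the solver certifies the
        last equilibrated load fraction instead of a bogus solution."""
        mesh = solve_cache.mesh(VariantId.WITH_SOC, self.H)
        mat = default_materials(True)
        with pytest.raises(fem.NonConvergenceError) as exc:
            assemble_and_solve(
                mesh, mat, solve_cache.bc,
                LoadCase(peak_pressure=3.0, n_steps=4),
                SolverOptions(max_halvings=1, max_iterations=10),
            )
        assert 0.0 < exc.value.last_converged_fraction < 1.0
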