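"""Shared fixtures: coarse meshes, block oracles and cached FEM solves.

The epiphysis solves are expensive, so they are computed lazily once per
session and shared across property and acceptance tests through the
``solve_cache`` fixture.
"""

from __future__ import annotations

import numpy as np
import pytest

from epimech import fem, geometry, stress
from epimech.geometry import EpiphysisParams, SubdomainLabel, VariantId
from epimech.mechtest import EpiphysisDims
from epimech.synthetic import gen_block_fixture


@pytest.fixture(scope="session")
def params() -> EpiphysisParams:
    return EpiphysisParams()


@pytest.fixture(scope="session")
def coarse_meshes(params):
    """h = 2 mm meshes for every variant (cheap, conforming, symmetric)."""
    out = {}
    for var in VariantId:
        out[var] = geometry.generate_mesh(geometry.build_geometry(params, var), 2.0)
    return out


@pytest.fixture(scope="session")
def block():
    """10 x 10 mm cartilage block with the plane-strain closed form."""
    return gen_block_fixture(10.0, 10.0, 6.0, 0.47, 0.01, target_h=1.25)


@pytest.fixture(scope="session")
def dims() -> EpiphysisDims:
    return EpiphysisDims(height=2.0, top_d1=4.0, top_d2=3.0, side_e1=3.5, side_e2=2.5)


class _SolveCache:
    """Lazily solves and post-processes epiphysis load cases, memoized."""

    def __init__(self, params: EpiphysisParams):
        self.params = params
        self.bc = fem.BoundaryConditions.epiphysis_default()
        self._meshes: dict = {}
        self._runs: dict = {}

    def mesh(self, variant: VariantId, h: float):
        key = (variant, h)
        if key not in self._meshes:
            self._meshes[key] = geometry.generate_mesh(
                geometry.build_geometry(self.params, variant), h
            )
        return self._meshes[key]

    def run(
        self,
        variant: VariantId,
        h: float,
        peak: float,
        angle: float = 90.0,
        wide: bool = False,
        small_strain: bool = False,
    ):
        key = (variant, h, peak, angle, wide, small_strain)
        if key not in self._runs:
            mesh = self.mesh(variant, h)
            mat = fem.default_materials(stiff_insert=variant is not VariantId.NO_SOC)
            lc = fem.LoadCase(
                peak_pressure=peak, sector_center_angle=angle, wide_support=wide
            )
            sol = fem.assemble_and_solve(
                mesh, mat, self.bc, lc, fem.SolverOptions(small_strain=small_strain)
            )
            tens = stress.second_pk_stress(sol, mesh, mat)
            sc = stress.scalar_measures(tens)
            band = mesh.elements_with_label(SubdomainLabel.GROWTH_PLATE_BAND)
            self._runs[key] = {
                "mesh": mesh,
                "sol": sol,
                "tensors": tens,
                "scalars": sc,
                "band": band,
                "deflection": stress.deflection(sol, mesh, lc),
                "band_summary": stress.zone_summary(sc, mesh, band, "band"),
                "thirds": {
                    k: stress.zone_summary(sc, mesh, v, k)
                    for k, v in geometry.band_thirds(mesh, band).items()
                },
            }
        return self._runs[key]


@pytest.fixture(scope="session")
def solve_cache(params) -> _SolveCache:
    return _SolveCache(params)
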