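"""Geometry construction and triangulation invariants."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from epimech.geometry import (
    EpiphysisParams,
    GeometryError,
    MeshingError,
    SubdomainLabel,
    VariantId,
    band_thirds,
    build_geometry,
    generate_mesh,
    zone_elements,
)


@pytest.fixture(scope="module")
def geoms(params):
    return {v: build_geometry(params, v) for v in VariantId}


class TestBuildGeometry:
    def test_area_conservation_shoelace(self, geoms):
        """Sum of subdomain areas equals the outer area for every variant."""
        for var, g in geoms.items():
            total = sum(p.area for ps in g.regions.values() for p in ps)
            assert total == pytest.approx(g.outer_area, rel=1e-9), var

    def test_variants_share_outer_geometry(self, geoms):
        areas = {v: g.outer_area for v, g in geoms.items()}
        ref = areas[VariantId.NO_SOC]
        assert all(a == pytest.approx(ref, rel=1e-12) for a in areas.values())

    def test_soc_variants_mesh_identical(self, geoms):
        """no_soc keeps the insert polygon (material decides stiffness)."""
        a = geoms[VariantId.NO_SOC].regions[SubdomainLabel.STIFF_INSERT]
        b = geoms[VariantId.WITH_SOC].regions[SubdomainLabel.STIFF_INSERT]
        assert len(a) == len(b) == 1
        assert a[0].equals(b[0])

    def test_protrusion_count_passthrough(self, params):
        g = build_geometry(params, VariantId.PROTRUSIONS_EXTENDED)
        assert len(g.regions[SubdomainLabel.STIFF_INSERT]) == params.protrusions_extended.count

    def test_five_labels_present(self, geoms):
        for g in geoms.values():
            present = {lab for lab, ps in g.regions.items() if ps}
            assert present == set(SubdomainLabel)

    def test_mirror_symmetry(self, geoms):
        import shapely

        for g in geoms.values():
            for lab, ps in g.regions.items():
                for p in ps:
                    mirrored = shapely.transform(p, lambda c: c * np.array([-1.0, 1.0]))
                    covered = any(
                        q.symmetric_difference(mirrored).area < 1e-6 * max(q.area, 1.0)
                        for q in ps
                    )
                    assert covered, (lab, p.bounds)

    def test_out_of_bounds_insert_rejected(self):
        p = EpiphysisParams(soc_center=(0.0, 60.0), soc_semi_axes=(12.0, 8.0))
        with pytest.raises(GeometryError):
            build_geometry(p, VariantId.WITH_SOC)

    def test_band_above_soc_rejected(self):
        p = EpiphysisParams(gp_band_y=55.0)
        with pytest.raises(GeometryError):
            build_geometry(p, VariantId.WITH_SOC)


class TestGenerateMesh:
    def test_unit_square_area(self):
        sq = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        mesh = generate_mesh([(SubdomainLabel.EPIPHYSEAL_CARTILAGE, sq)], 0.5)
        areas = mesh.signed_areas()
        assert np.all(areas > 0)
        assert areas.sum() == pytest.approx(1.0, rel=1e-9)

    def test_labels_match_containing_polygon(self, geoms):
        import shapely

        g = geoms[VariantId.WITH_SOC]
        mesh = generate_mesh(g, 1.0)
        cen = mesh.centroids()
        for lab, ps in g.regions.items():
            want = np.zeros(len(cen), dtype=bool)
            for p in ps:
                want |= shapely.contains_xy(p, cen[:, 0], cen[:, 1])
            got = np.zeros(len(cen), dtype=bool)
            got[mesh.elements_with_label(lab)] = True
            # every element whose centroid is strictly inside a region's
            # polygon must carry that region's label
            assert np.all(got[want] | ~want[want])
            assert np.array_equal(got, want)

    def test_refinement_increases_element_count(self, geoms):
        g = geoms[VariantId.WITH_SOC]
        n1 = generate_mesh(g, 2.0).n_elements
        n2 = generate_mesh(g, 1.0).n_elements
        assert n2 > n1

    def test_circumradius_bound(self, coarse_meshes):
        for var, mesh in coarse_meshes.items():
            assert mesh.circumradii().max() <= 2.0 * mesh.target_edge_length, var

    def test_arc_nodes_on_circle(self, coarse_meshes, params):
        for mesh in coarse_meshes.values():
            cx, cy = params.arc_center
            arcn = mesh.boundary_nodes("top_arc")
            r = np.hypot(mesh.nodes[arcn, 0] - cx, mesh.nodes[arcn, 1] - cy)
            assert np.max(np.abs(r - params.top_radius)) <= 1e-6 * params.top_radius

    def test_boundary_single_closed_loop(self, coarse_meshes):
        for mesh in coarse_meshes.values():
            deg = {}
            for a, b in mesh.boundary_edges:
                deg[a] = deg.get(a, 0) + 1
                deg[b] = deg.get(b, 0) + 1
            assert all(d == 2 for d in deg.values())
            # connectivity: walk the loop and visit every boundary node
            adj = {}
            for a, b in mesh.boundary_edges:
                adj.setdefault(int(a), []).append(int(b))
                adj.setdefault(int(b), []).append(int(a))
            start = next(iter(adj))
            seen = {start}
            prev, cur = None, start
            while True:
                nxt = [n for n in adj[cur] if n != prev]
                prev, cur = cur, nxt[0]
                if cur == start:
                    break
                seen.add(cur)
            assert seen == set(adj)

    def test_mesh_exactly_mirror_symmetric(self, coarse_meshes):
        for mesh in coarse_meshes.values():
            flipped = mesh.nodes * np.array([-1.0, 1.0])
            key = {(round(x, 9), round(y, 9)) for x, y in mesh.nodes}
            fkey = {(round(x, 9), round(y, 9)) for x, y in flipped}
            assert key == fkey

    def test_invalid_target_edge(self, geoms):
        with pytest.raises(MeshingError):
            generate_mesh(geoms[VariantId.WITH_SOC], -1.0)


class TestZoneSelection:
    def test_whole_domain_band(self, coarse_meshes):
        mesh = coarse_meshes[VariantId.WITH_SOC]
        sel = zone_elements(mesh, (-1e9, 1e9))
        assert len(sel) == mesh.n_elements

    def test_band_above_domain_is_empty(self, coarse_meshes):
        mesh = coarse_meshes[VariantId.WITH_SOC]
        sel = zone_elements(mesh, (1000.0, 2000.0))
        assert len(sel) == 0

    def test_thirds_partition_band(self, coarse_meshes):
        mesh = coarse_meshes[VariantId.WITH_SOC]
        band = mesh.elements_with_label(SubdomainLabel.GROWTH_PLATE_BAND)
        thirds = band_thirds(mesh, band)
        union = np.concatenate(list(thirds.values()))
        assert sorted(union) == sorted(band)
        assert len(union) == len(set(union))
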