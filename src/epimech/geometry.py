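"""Parametric 2D epiphysis geometry and conforming labeled triangulation.

The simulated domain is an idealized long-bone end: a semicircular
cartilaginous head sitting on a trapezoidal shaft of bone.  Five tissue
subdomains are distinguished (epiphyseal cartilage, a stiff insert standing
for the secondary ossification center or for ossified protrusions, the
growth-plate band of hypertrophic chondrocytes, cortical bone, and
metaphyseal bone).  Model variants share the outer geometry and differ only
in which candidate regions exist and are mapped stiff, so cross-variant
stress comparisons are geometry-controlled.

All lengths are millimetres; the coordinate origin is at the bottom-center
of the shaft with y pointing up.  Angles on the semicircular top arc are in
degrees measured from the +x axis about the arc center, so the apex is 90°.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon, box
from shapely.ops import polygonize, unary_union

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryError",
    "MeshingError",
    "SubdomainLabel",
    "VariantId",
    "ProtrusionSpec",
    "EpiphysisParams",
    "LabeledGeometry",
    "PlanarMesh",
    "build_geometry",
    "generate_mesh",
    "zone_elements",
    "band_thirds",
]


class GeometryError(ValueError):
    """Invalid or inconsistent domain geometry."""


class MeshingError(RuntimeError):
    """Triangulation failed or produced an invalid mesh."""


class SubdomainLabel(Enum):
    EPIPHYSEAL_CARTILAGE = "epiphyseal_cartilage"
    STIFF_INSERT = "stiff_insert"
    GROWTH_PLATE_BAND = "growth_plate_band"
    CORTICAL_BONE = "cortical_bone"
    METAPHYSEAL_BONE = "metaphyseal_bone"


class VariantId(Enum):
    NO_SOC = "no_soc"
    WITH_SOC = "with_soc"
    PROTRUSIONS_SMALL = "protrusions_small"
    PROTRUSIONS_EXTENDED = "protrusions_extended"


#: variants whose stiff insert is the semi-elliptical ossification center
_SOC_VARIANTS = (VariantId.NO_SOC, VariantId.WITH_SOC)


@dataclass(frozen=True)
class ProtrusionSpec:
    """Finger-like ossified protrusions rising from the metaphyseal side.

    Depths are not dimensioned in any source; the defaults (4 mm for the
    small variant, 10 mm for the extended one) visually match renderings of
    stem-tetrapod versus archosaur epiphyses and are fully configurable.
    """

    count: int = 5
    depth: float = 10.0
    width: float = 2.0
    spacing: float = 5.0

    def validate(self) -> None:
        if self.count < 1:
            raise GeometryError("protrusion count must be >= 1")
        for name in ("depth", "width", "spacing"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"protrusion {name} must be > 0")
        if self.width >= self.spacing:
            raise GeometryError("protrusion width must be < spacing")

    def centers(self) -> np.ndarray:
        """Finger center abscissae, symmetric about the midline."""
        k = np.arange(self.count, dtype=float)
        return (k - (self.count - 1) / 2.0) * self.spacing


@dataclass(frozen=True)
class EpiphysisParams:
    """Outer dimensions and subdomain placement of the epiphysis model.

    The printed outer dimensions are total height 66 mm, top radius 17 mm,
    bottom width 25 mm, a cortical wall 2.5 mm wide measured horizontally
    and an out-of-plane thickness of 1 mm.  The internal partition (SOC
    semi-ellipse, growth-plate band) is a reconstruction with configurable
    placement.
    """

    total_height: float = 66.0
    top_radius: float = 17.0
    bottom_width: float = 25.0
    cortical_width: float = 2.5
    thickness: float = 1.0
    gp_band_y: float = 50.5
    gp_band_height: float = 3.0
    soc_center: tuple[float, float] = (0.0, 53.0)
    soc_semi_axes: tuple[float, float] = (12.0, 8.0)
    protrusions_small: ProtrusionSpec = field(
        default_factory=lambda: ProtrusionSpec(depth=4.0)
    )
    protrusions_extended: ProtrusionSpec = field(
        default_factory=lambda: ProtrusionSpec(depth=10.0)
    )
    #: segments used to discretize the semicircular arc / SOC semi-ellipse
    arc_segments: int = 96

    @property
    def arc_center(self) -> tuple[float, float]:
        return (0.0, self.total_height - self.top_radius)

    def validate(self) -> None:
        for name in (
            "total_height",
            "top_radius",
            "bottom_width",
            "cortical_width",
            "thickness",
            "gp_band_height",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if self.top_radius > self.bottom_width:
            raise GeometryError("top_radius must not exceed bottom_width")
        yc = self.arc_center[1]
        if yc <= 0:
            raise GeometryError("top_radius must be smaller than total_height")
        if self.cortical_width >= self.bottom_width / 2.0:
            raise GeometryError("cortical_width must be < bottom_width / 2")
        if self.arc_segments < 8:
            raise GeometryError("arc_segments must be >= 8")
        self.protrusions_small.validate()
        self.protrusions_extended.validate()
        # SOC semi-ellipse strictly inside the cartilage head
        cx, cy = self.soc_center
        a, b = self.soc_semi_axes
        if a <= 0 or b <= 0:
            raise GeometryError("soc semi-axes must be > 0")
        t = np.linspace(0.0, math.pi, 181)
        ex = cx + a * np.cos(t)
        ey = cy + b * np.sin(t)
        r2 = ex**2 + (ey - yc) ** 2
        if cy < yc or np.any(r2 >= self.top_radius**2):
            raise GeometryError("soc insert does not lie strictly inside the head")
        # band below the SOC
        band_top = self.gp_band_y + self.gp_band_height / 2.0
        band_bot = self.gp_band_y - self.gp_band_height / 2.0
        if band_top > cy:
            raise GeometryError("gp band must lie below the soc insert region")
        if band_bot < yc - 1e-9:
            raise GeometryError("gp band must lie within the cartilage head")


@dataclass
class LabeledGeometry:
    """Output of :func:`build_geometry`: labeled regions plus noded faces.

    ``faces`` are the atomic polygons of the planar arrangement of all
    region boundaries: adjacent faces share identical vertex chains, which
    is what makes the triangulation conform across material interfaces.
    """

    params: EpiphysisParams
    variant: VariantId
    regions: dict[SubdomainLabel, list[Polygon]]
    faces: list[tuple[SubdomainLabel, Polygon]]
    outer: Polygon

    @property
    def outer_area(self) -> float:
        return self.outer.area

    def region_area(self, label: SubdomainLabel) -> float:
        return sum(p.area for p in self.regions.get(label, []))


def _semicircle(r: float, yc: float, n: int) -> Polygon:
    t = np.linspace(0.0, math.pi, n + 1)
    pts = np.column_stack([r * np.cos(t), yc + r * np.sin(t)])
    return Polygon(pts)


def _half_ellipse(cx: float, cy: float, a: float, b: float, n: int) -> Polygon:
    t = np.linspace(0.0, math.pi, n + 1)
    pts = np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)])
    return Polygon(pts)


def build_geometry(
    params: EpiphysisParams, variant: VariantId
) -> LabeledGeometry:
    """Construct the labeled subdomain polygons for one model variant.

    All variants share the outer geometry.  For the SOC variants the stiff
    insert is the semi-ellipse (the ``no_soc`` variant keeps the polygon and
    simply assigns it cartilage material downstream, so with/without
    comparisons are mesh-identical).  Protrusion variants replace it by
    finger polygons rising from the head base through the growth-plate band
    into the cartilage; the band subdomain is then the strip minus the
    fingers — the "hypertrophic zone free of bony elements" used for
    cross-variant comparison.
    """
    params.validate()
    if not isinstance(variant, VariantId):
        variant = VariantId(variant)

    r = params.top_radius
    yc = params.arc_center[1]
    hb = params.bottom_width / 2.0
    big = 10.0 * (r + params.total_height)

    head = _semicircle(r, yc, params.arc_segments)
    # trapezoidal shaft, flush with the head at y = yc
    shaft = Polygon([(-hb, 0.0), (hb, 0.0), (r, yc), (-r, yc)])
    w = params.cortical_width
    cort_r = Polygon([(hb - w, 0.0), (hb, 0.0), (r, yc), (r - w, yc)])
    cort_l = shapely.transform(cort_r, lambda p: p * np.array([-1.0, 1.0]))
    metaph = Polygon([(-(hb - w), 0.0), (hb - w, 0.0), (r - w, yc), (-(r - w), yc)])

    band_bot = params.gp_band_y - params.gp_band_height / 2.0
    band_top = params.gp_band_y + params.gp_band_height / 2.0
    band_strip = head.intersection(box(-big, band_bot, big, band_top))

    if variant in _SOC_VARIANTS:
        cx, cy = params.soc_center
        a, b = params.soc_semi_axes
        insert_polys = [_half_ellipse(cx, cy, a, b, params.arc_segments)]
        band = band_strip
    else:
        spec = (
            params.protrusions_small
            if variant is VariantId.PROTRUSIONS_SMALL
            else params.protrusions_extended
        )
        insert_polys = []
        for xc in spec.centers():
            finger = box(xc - spec.width / 2.0, yc, xc + spec.width / 2.0, yc + spec.depth)
            if not head.covers(finger):
                raise GeometryError(
                    f"stiff_insert finger at x={xc:g} extends outside the cartilage head"
                )
            insert_polys.append(finger)
        fingers = unary_union(insert_polys)
        band = band_strip.difference(fingers)

    insert_union = unary_union(insert_polys)
    cartilage = head.difference(band_strip).difference(insert_union)

    regions: dict[SubdomainLabel, list[Polygon]] = {
        SubdomainLabel.EPIPHYSEAL_CARTILAGE: _as_polys(cartilage),
        SubdomainLabel.STIFF_INSERT: insert_polys,
        SubdomainLabel.GROWTH_PLATE_BAND: _as_polys(band),
        SubdomainLabel.CORTICAL_BONE: [cort_l, cort_r],
        SubdomainLabel.METAPHYSEAL_BONE: [metaph],
    }

    outer = unary_union([head, shaft])
    if not isinstance(outer, Polygon):
        raise GeometryError("outer boundary is not a single polygon")

    _check_partition(regions, outer)
    faces = _node_faces(regions, outer)
    return LabeledGeometry(
        params=params, variant=variant, regions=regions, faces=faces, outer=outer
    )


def _as_polys(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    return [g for g in geom.geoms if isinstance(g, Polygon)]


def _check_partition(
    regions: Mapping[SubdomainLabel, list[Polygon]], outer: Polygon
) -> None:
    labeled = [(lab, p) for lab, ps in regions.items() for p in ps]
    total = sum(p.area for _, p in labeled)
    if not math.isclose(total, outer.area, rel_tol=1e-9):
        raise GeometryError(
            f"subdomain areas ({total:.12g}) do not tile the outer domain "
            f"({outer.area:.12g})"
        )
    for i, (lab_i, pi) in enumerate(labeled):
        for lab_j, pj in labeled[i + 1 :]:
            inter = pi.intersection(pj).area
            if inter > 1e-9 * outer.area:
                raise GeometryError(
                    f"subdomains {lab_i.value} and {lab_j.value} overlap "
                    f"(area {inter:.3g})"
                )


def _node_faces(
    regions: Mapping[SubdomainLabel, list[Polygon]], outer: Polygon
) -> list[tuple[SubdomainLabel, Polygon]]:
    """Node all region boundaries and split the domain into atomic faces.

    Polygonizing the unioned linework guarantees that two faces meeting
    along an interface carry identical vertex chains there.
    """
    lines = unary_union(
        [p.boundary for ps in regions.values() for p in ps] + [outer.boundary]
    )
    faces = [f for f in polygonize(lines) if isinstance(f, Polygon)]
    # the polygonizer emits enclosed rings as their own faces; carve any face
    # that fully contains another so areas partition exactly
    carved: list[Polygon] = []
    for f in faces:
        inner = [g for g in faces if g is not f and f.contains(g)]
        if inner:
            f = f.difference(unary_union(inner))
        carved.extend(_as_polys(f))
    total = sum(f.area for f in carved)
    if not math.isclose(total, outer.area, rel_tol=1e-9):
        raise GeometryError("planar arrangement does not tile the outer domain")

    out: list[tuple[SubdomainLabel, Polygon]] = []
    for f in carved:
        pt = f.representative_point()
        owner = None
        for lab, ps in regions.items():
            if any(p.covers(pt) for p in ps):
                owner = lab
                break
        if owner is None:
            raise GeometryError("face could not be assigned to a subdomain")
        out.append((owner, f))
    return out


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------


@dataclass
class PlanarMesh:
    """Labeled reference-configuration triangulation.

    ``triangles`` are counter-clockwise node-index triples; ``labels`` holds
    one :class:`SubdomainLabel` index per triangle (see ``label_order``).
    Boundary edges carry a tag; nodes on the top arc additionally carry
    their polar angle about the arc center, in degrees.
    """

    nodes: np.ndarray  # (N, 2) float
    triangles: np.ndarray  # (M, 3) int
    labels: np.ndarray  # (M,) int, index into label_order
    label_order: list[SubdomainLabel]
    boundary_edges: np.ndarray  # (B, 2) int
    boundary_tags: list[str]  # len B
    arc_center: tuple[float, float] | None = None
    arc_radius: float | None = None
    target_edge_length: float | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_label(self, e: int) -> SubdomainLabel:
        return self.label_order[self.labels[e]]

    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def areas(self) -> np.ndarray:
        return self.signed_areas()

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def elements_with_label(self, label: SubdomainLabel) -> np.ndarray:
        idx = self.label_order.index(label)
        return np.flatnonzero(self.labels == idx)

    def boundary_nodes(self, tag: str | None = None) -> np.ndarray:
        if tag is None:
            edges = self.boundary_edges
        else:
            keep = [i for i, t in enumerate(self.boundary_tags) if t == tag]
            edges = self.boundary_edges[keep]
        return np.unique(edges)

    def arc_angles(self) -> dict[int, float]:
        """Polar angle (degrees, about the arc center) of each top-arc node."""
        if self.arc_center is None:
            return {}
        cx, cy = self.arc_center
        out = {}
        for n in self.boundary_nodes("top_arc"):
            x, y = self.nodes[n]
            out[int(n)] = math.degrees(math.atan2(y - cy, x - cx))
        return out

    def circumradii(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        a = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
        b = np.linalg.norm(p[:, 2] - p[:, 1], axis=1)
        c = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
        area = np.abs(self.signed_areas())
        return a * b * c / np.maximum(4.0 * area, 1e-300)

    def validate(self) -> None:
        if np.any(self.signed_areas() <= 0):
            raise MeshingError("mesh contains non-positively-oriented triangles")
        # boundary edges form a single closed loop
        deg: dict[int, int] = {}
        for e in self.boundary_edges:
            for n in e:
                deg[int(n)] = deg.get(int(n), 0) + 1
        if any(d != 2 for d in deg.values()):
            raise MeshingError("boundary edge set is not a union of closed loops")
        if self.arc_center is not None and self.arc_radius is not None:
            cx, cy = self.arc_center
            arcn = self.boundary_nodes("top_arc")
            if len(arcn):
                rr = np.hypot(
                    self.nodes[arcn, 0] - cx, self.nodes[arcn, 1] - cy
                )
                if np.max(np.abs(rr - self.arc_radius)) > 1e-6 * self.arc_radius:
                    raise MeshingError("top-arc nodes are not on the arc circle")


_LABEL_ORDER = list(SubdomainLabel)


def _canonical_segment_points(p: np.ndarray, q: np.ndarray, h: float) -> np.ndarray:
    """Interior subdivision points of segment pq at spacing <= h.

    The segment is canonically oriented before subdividing so both faces
    sharing it produce bit-identical point coordinates.
    """
    swap = (p[0], p[1]) > (q[0], q[1])
    a, b = (q, p) if swap else (p, q)
    # rounding (not ceiling) avoids splitting segments already near h,
    # which would insert collinear points on polygonal arc chords
    n = max(1, round(float(np.hypot(*(b - a))) / h))
    t = np.arange(1, n) / n
    return a * (1.0 - t[:, None]) + b * t[:, None]


def _densify_ring(coords: np.ndarray, h: float) -> np.ndarray:
    pts = []
    for i in range(len(coords) - 1):
        p, q = coords[i], coords[i + 1]
        pts.append(p[None, :])
        interior = _canonical_segment_points(p, q, h)
        if len(interior):
            # preserve traversal order regardless of canonical orientation
            if (p[0], p[1]) > (q[0], q[1]):
                interior = interior[::-1]
            pts.append(interior)
    return np.vstack(pts)


def _interior_grid(
    poly: Polygon, h: float, margin: float, shift: tuple[float, float]
) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    dy = h * math.sqrt(3.0) / 2.0
    ys = np.arange(miny + dy / 2 + shift[1], maxy, dy)
    pts = []
    for j, y in enumerate(ys):
        off = (j % 2) * h / 2.0
        xs = np.arange(minx + h / 2 + off + shift[0], maxx, h)
        if len(xs):
            pts.append(np.column_stack([xs, np.full(len(xs), y)]))
    if not pts:
        return np.empty((0, 2))
    cand = np.vstack(pts)
    inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
    cand = cand[inside]
    if len(cand) == 0:
        return cand
    d = shapely.distance(shapely.points(cand), poly.boundary)
    return cand[d >= margin * h]


def _triangulate_face(poly: Polygon, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate one polygon (possibly with holes) at target edge h.

    Boundary rings are densified with the canonical per-segment rule (so
    adjacent faces conform); interior points come from a hexagonal lattice.
    A Delaunay triangulation restricted to the polygon is accepted only if
    it tiles the polygon area to 1e-9 relative; otherwise the lattice is
    shifted / pulled back from the boundary and the attempt repeated.
    """
    rings = [np.asarray(poly.exterior.coords)] + [
        np.asarray(r.coords) for r in poly.interiors
    ]
    # boundary subdivision is fixed by the global h (identical on both sides
    # of every interface — conformity depends on it); only the interior
    # lattice may refine when a face is too thin or curved to tile at h
    bpts = np.vstack([_densify_ring(r, h) for r in rings])
    for h_int in (h, h / 2.0, h / 4.0):
        attempts = [
            (0.65, (0.0, 0.0)),
            (0.75, (0.31 * h_int, 0.17 * h_int)),
            (0.85, (0.13 * h_int, 0.41 * h_int)),
            (0.95, (0.47 * h_int, 0.29 * h_int)),
        ]
        pts_simp = _try_attempts(poly, h_int, bpts, attempts)
        if pts_simp is not None:
            return pts_simp
    raise MeshingError(
        f"could not tile polygon (area {poly.area:.3g}) at h={h:g}"
    )


def _try_attempts(poly: Polygon, h: float, bpts: np.ndarray, attempts):
    for margin, shift in attempts:
        ipts = _interior_grid(poly, h, margin, shift)
        pts = np.vstack([bpts, ipts]) if len(ipts) else bpts
        if len(pts) < 3:
            raise MeshingError("degenerate polygon input: fewer than 3 points")
        try:
            tri = Delaunay(pts)
        except Exception as exc:  # qhull degeneracies
            raise MeshingError(f"Delaunay triangulation failed: {exc}") from exc
        simp = tri.simplices
        p = pts[simp]
        area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
            p[:, 2, 0] - p[:, 0, 0]
        ) * (p[:, 1, 1] - p[:, 0, 1])
        cen = p.mean(axis=1)
        lmax2 = np.max(
            np.sum(np.diff(p[:, [0, 1, 2, 0], :], axis=1) ** 2, axis=2), axis=1
        )
        # quality filter: near-collinear point triples (polygonal-arc chords)
        # produce slivers whose area is vanishing relative to their edges
        keep = (np.abs(area2) > 1e-7 * lmax2) & shapely.contains_xy(
            poly, cen[:, 0], cen[:, 1]
        )
        simp = simp[keep]
        total = float(np.abs(area2[keep]).sum() / 2.0)
        if abs(total - poly.area) <= 1e-9 * max(poly.area, 1.0):
            # fix orientation to CCW
            flip = area2[keep] < 0
            simp[flip] = simp[flip][:, ::-1]
            return pts, simp
    return None


def _merge_meshes(
    parts: list[tuple[np.ndarray, np.ndarray, int]], tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate per-face meshes, welding coincident nodes."""
    all_pts = np.vstack([p for p, _, _ in parts])
    tris = []
    labels = []
    off = 0
    for p, s, lab in parts:
        tris.append(s + off)
        labels.append(np.full(len(s), lab, dtype=np.int64))
        off += len(p)
    tri = np.vstack(tris)
    labels = np.concatenate(labels)

    tree = cKDTree(all_pts)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(all_pts))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    root = np.array([find(i) for i in range(len(all_pts))])
    uniq, inv = np.unique(root, return_inverse=True)
    nodes = all_pts[uniq]
    tri = inv[tri]
    return nodes, tri, labels


def _tag_boundary(
    nodes: np.ndarray,
    tri: np.ndarray,
    params: EpiphysisParams | None,
) -> tuple[np.ndarray, list[str]]:
    edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    bedges = edges[idx[counts == 1]]

    tags: list[str] = []
    if params is None:
        for e in bedges:
            tags.append("outer")
        return bedges, tags

    r = params.top_radius
    cx, cy = params.arc_center
    hb = params.bottom_width / 2.0
    tol = 1e-6 * r
    for e in bedges:
        mx, my = nodes[e].mean(axis=0)
        if my < tol:
            tags.append("bottom")
        elif abs(math.hypot(mx - cx, my - cy) - r) < r * 5e-3 and my > cy - tol:
            tags.append("top_arc")
        else:
            # slanted cortical sides: x = +-(hb + (r - hb) * y / yc)
            xs = hb + (r - hb) * my / cy
            if abs(mx - xs) < 1e-6 * r:
                tags.append("cortical_outer_right")
            elif abs(mx + xs) < 1e-6 * r:
                tags.append("cortical_outer_left")
            else:
                tags.append("outer")
    return bedges, tags


def _mirror_x(poly: Polygon) -> Polygon:
    return shapely.transform(poly, lambda p: p * np.array([-1.0, 1.0]))


def generate_mesh(
    geometry: LabeledGeometry | Sequence[tuple[SubdomainLabel, Polygon]],
    target_edge_length: float,
    *,
    symmetric: bool | None = None,
) -> PlanarMesh:
    """Produce a conforming labeled triangulation of the labeled faces.

    For mirror-symmetric geometries only the x >= 0 half of every face is
    triangulated and then reflected, which makes the mesh exactly symmetric
    about the vertical centerline (so symmetric loads produce symmetric
    discrete solutions to solver precision).
    """
    if target_edge_length <= 0:
        raise MeshingError("target_edge_length must be > 0")
    h = float(target_edge_length)

    params: EpiphysisParams | None = None
    if isinstance(geometry, LabeledGeometry):
        faces = geometry.faces
        params = geometry.params
    else:
        regions: dict[SubdomainLabel, list[Polygon]] = {}
        for lab, poly in geometry:
            regions.setdefault(lab, []).append(poly)
        outer = unary_union([p for ps in regions.values() for p in ps])
        outer_polys = _as_polys(outer)
        if len(outer_polys) != 1:
            raise MeshingError("labeled polygons do not form a single domain")
        faces = _node_faces(regions, outer_polys[0])

    if symmetric is None:
        union = unary_union([f for _, f in faces])
        symmetric = (
            union.symmetric_difference(_mirror_x(union)).area < 1e-9 * union.area
        )

    weld_tol = min(1e-8, 1e-4 * h)
    parts: list[tuple[np.ndarray, np.ndarray, int]] = []
    label_index = {lab: i for i, lab in enumerate(_LABEL_ORDER)}
    for lab, poly in faces:
        lab_i = label_index.setdefault(lab, len(label_index))
        if symmetric:
            bigx = poly.bounds[2] - poly.bounds[0] + abs(poly.bounds[2]) + 1.0
            miny, maxy = poly.bounds[1] - 1.0, poly.bounds[3] + 1.0
            right = poly.intersection(box(0.0, miny, bigx, maxy))
            for piece in _as_polys(right):
                if piece.area < 1e-12:
                    continue
                pts, simp = _triangulate_face(piece, h)
                pts = pts.copy()
                pts[np.abs(pts[:, 0]) < weld_tol, 0] = 0.0
                parts.append((pts, simp, lab_i))
                mpts = pts * np.array([-1.0, 1.0])
                mpts[np.abs(mpts[:, 0]) < weld_tol, 0] = 0.0
                parts.append((mpts, simp[:, ::-1].copy(), lab_i))
        else:
            pts, simp = _triangulate_face(poly, h)
            parts.append((pts, simp, lab_i))

    order = sorted(label_index, key=label_index.get)
    nodes, tri, labels = _merge_meshes(parts, weld_tol)
    bedges, tags = _tag_boundary(nodes, tri, params)

    mesh = PlanarMesh(
        nodes=nodes,
        triangles=tri,
        labels=labels,
        label_order=list(order),
        boundary_edges=bedges,
        boundary_tags=tags,
        arc_center=params.arc_center if params is not None else None,
        arc_radius=params.top_radius if params is not None else None,
        target_edge_length=h,
    )
    # snap arc nodes exactly onto the circle (polygonal sagitta correction)
    if params is not None:
        arcn = mesh.boundary_nodes("top_arc")
        if len(arcn):
            cx, cy = params.arc_center
            v = mesh.nodes[arcn] - (cx, cy)
            rr = np.linalg.norm(v, axis=1)
            mesh.nodes[arcn] = (cx, cy) + v * (params.top_radius / rr)[:, None]
    mesh.validate()
    return mesh


def zone_elements(
    mesh: PlanarMesh,
    y_interval: tuple[float, float],
    x_interval: tuple[float, float] | None = None,
) -> np.ndarray:
    """Elements whose centroid lies inside the given band.

    An empty selection is returned as an empty index array (with a logged
    warning), never raised.
    """
    c = mesh.centroids()
    sel = (c[:, 1] >= y_interval[0]) & (c[:, 1] <= y_interval[1])
    if x_interval is not None:
        sel &= (c[:, 0] >= x_interval[0]) & (c[:, 0] <= x_interval[1])
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        logger.warning(
            "zone selection y=%s x=%s matched no elements", y_interval, x_interval
        )
    return idx


def band_thirds(
    mesh: PlanarMesh, elements: np.ndarray
) -> dict[str, np.ndarray]:
    """Partition band elements into left/middle/right equal-width thirds.

    Widths are equal in x over the selection's centroid extent; every
    element lands in exactly one third.
    """
    elements = np.asarray(elements)
    if len(elements) == 0:
        logger.warning("band_thirds called with an empty element set")
        return {"left": elements, "middle": elements, "right": elements}
    cx = mesh.centroids()[elements, 0]
    lo, hi = float(cx.min()), float(cx.max())
    width = (hi - lo) / 3.0
    b1, b2 = lo + width, lo + 2.0 * width
    left = elements[cx < b1]
    middle = elements[(cx >= b1) & (cx < b2)]
    right = elements[cx >= b2]
    return {"left": left, "middle": middle, "right": right}
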