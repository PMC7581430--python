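"""Plane-strain finite-deformation elastostatics on the labeled mesh.

Total-Lagrangian formulation with a Saint Venant–Kirchhoff material (linear
in Green–Lagrange strain, so "linearly elastic" constants combined with
nonlinear strains), solved by incremental Newton iteration.  Elements are
6-node quadratic triangles with 3-point quadrature — near-incompressible
cartilage (ν = 0.47) locks badly with linear triangles.

The load is a pressure applied to a sector of the semicircular top arc,
maximal at the sector center and falling quadratically to zero at the
sector borders; by default it is a follower load (direction and magnitude
track the deforming surface), with a dead-load option for comparison.
A small-strain path (linear kinematics) is provided for verification
against closed-form solutions and for low-load linearization checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import PlanarMesh, SubdomainLabel

logger = logging.getLogger(__name__)

__all__ = [
    "IncompressibilityError",
    "NonConvergenceError",
    "Material",
    "MaterialMap",
    "lame_parameters",
    "LoadCase",
    "UniformPressure",
    "sector_pressure",
    "DirichletBC",
    "BoundaryConditions",
    "SolverOptions",
    "Solution",
    "QuadraticMesh",
    "make_quadratic",
    "assemble_and_solve",
    "default_materials",
]


class IncompressibilityError(ValueError):
    """Poisson ratio at or beyond the incompressible limit."""


class NonConvergenceError(RuntimeError):
    def __init__(self, msg: str, last_converged_fraction: float = 0.0):
        super().__init__(msg)
        self.last_converged_fraction = last_converged_fraction


def lame_parameters(E: float, nu: float) -> tuple[float, float]:
    """Lamé constants (λ, μ) from Young's modulus and Poisson ratio.

    λ = Eν/((1+ν)(1−2ν)),  μ = E/(2(1+ν)).  ν must be < 0.5.
    """
    if E <= 0:
        raise ValueError("Young's modulus must be > 0")
    if not 0.0 <= nu < 0.5:
        raise IncompressibilityError(f"Poisson ratio {nu} must be in [0, 0.5)")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


@dataclass(frozen=True)
class Material:
    """Isotropic material, MPa."""

    E: float
    nu: float

    @property
    def lame(self) -> tuple[float, float]:
        return lame_parameters(self.E, self.nu)


#: printed constants: cartilage E_C = 6 MPa, ν_C = 0.47; stiff (SOC /
#: dense cancellous bone) E_D = 500 MPa, ν_D = 0.20.  Cortical and
#: metaphyseal values are reconstructions (not printed): cortical bone at
#: 5 GPa and metaphyseal bone taken equal to dense cancellous bone.
CARTILAGE = Material(E=6.0, nu=0.47)
STIFF_BONE = Material(E=500.0, nu=0.20)
CORTICAL = Material(E=5000.0, nu=0.30)


class MaterialMap(dict):
    """Per-subdomain material assignment with derived Lamé constants."""

    def lame_arrays(self, mesh: PlanarMesh) -> tuple[np.ndarray, np.ndarray]:
        lam = np.empty(mesh.n_elements)
        mu = np.empty(mesh.n_elements)
        for i, lab in enumerate(mesh.label_order):
            m = self[lab]
            sel = mesh.labels == i
            lam[sel], mu[sel] = m.lame
        return lam, mu


def default_materials(stiff_insert: bool = True) -> MaterialMap:
    """Default tissue map; ``stiff_insert=False`` maps the insert to
    cartilage, realizing the SOC-free model on identical geometry."""
    logger.info(
        "materials: cortical/metaphyseal values are reconstructions "
        "(cortical E=5000 MPa nu=0.30, metaphyseal = dense cancellous bone)"
    )
    return MaterialMap(
        {
            SubdomainLabel.EPIPHYSEAL_CARTILAGE: CARTILAGE,
            SubdomainLabel.GROWTH_PLATE_BAND: CARTILAGE,
            SubdomainLabel.STIFF_INSERT: STIFF_BONE if stiff_insert else CARTILAGE,
            SubdomainLabel.CORTICAL_BONE: CORTICAL,
            SubdomainLabel.METAPHYSEAL_BONE: STIFF_BONE,
        }
    )


@dataclass(frozen=True)
class LoadCase:
    """Sector pressure on the top arc.

    ``sector_center_angle`` is in degrees on the arc (90 = vertical apex,
    45 = angled load from the right).  The profile is quadratic, maximal at
    the center, zero at the sector borders.  ``wide_support`` switches to
    the alternative reading in which the profile reaches zero only at the
    borders of the two *neighboring* 45° sectors (135° total support).
    """

    peak_pressure: float  # MPa
    sector_center_angle: float = 90.0
    sector_half_width: float = 22.5
    follower: bool = True
    n_steps: int | None = None
    wide_support: bool = False

    def __post_init__(self) -> None:
        if self.peak_pressure < 0:
            raise ValueError("peak_pressure must be >= 0")
        if not 0.0 < self.sector_half_width <= 90.0:
            raise ValueError("sector_half_width must be in (0, 90]")

    @property
    def support_half_width(self) -> float:
        return self.sector_half_width * (3.0 if self.wide_support else 1.0)


def sector_pressure(theta_deg: float | np.ndarray, lc: LoadCase) -> np.ndarray:
    """Quadratic sector pressure profile p(θ), clamped to zero outside."""
    th = np.asarray(theta_deg, dtype=float)
    delta = lc.support_half_width
    s = (th - lc.sector_center_angle) / delta
    return lc.peak_pressure * np.maximum(0.0, 1.0 - s * s)


@dataclass(frozen=True)
class UniformPressure:
    """Uniform pressure on a tagged straight boundary (verification loads)."""

    pressure: float  # MPa
    edge_tag: str = "top"
    follower: bool = False
    n_steps: int | None = None

    @property
    def peak_pressure(self) -> float:
        return self.pressure


@dataclass(frozen=True)
class DirichletBC:
    """Fixed displacement component on a tagged node set.

    ``component`` is 0 (x) or 1 (y); ``value`` is a constant or a callable
    value(x, y) evaluated at reference coordinates.  ``tag`` may be a
    boundary tag or "__all__" for every boundary node.
    """

    tag: str
    component: int
    value: float | Callable[[np.ndarray, np.ndarray], np.ndarray] = 0.0


@dataclass(frozen=True)
class BoundaryConditions:
    dirichlet: tuple[DirichletBC, ...]
    pin_nodes: tuple[tuple[int, int], ...] = ()  # (node, component) extra pins

    @staticmethod
    def epiphysis_default() -> "BoundaryConditions":
        """Zero vertical displacement on the bottom edge, zero horizontal
        displacement on the outer cortical edges."""
        return BoundaryConditions(
            dirichlet=(
                DirichletBC("bottom", 1, 0.0),
                DirichletBC("cortical_outer_left", 0, 0.0),
                DirichletBC("cortical_outer_right", 0, 0.0),
            )
        )


@dataclass(frozen=True)
class SolverOptions:
    tolerance: float = 1e-8
    max_iterations: int = 25
    n_steps: int | None = None
    small_strain: bool = False
    max_halvings: int = 4
    max_line_search: int = 8


@dataclass
class StepRecord:
    load_fraction: float
    iterations: int
    residuals: list[float]


@dataclass
class Solution:
    """Converged displacement field on the quadratic mesh."""

    qmesh: "QuadraticMesh"
    u: np.ndarray  # (Nq, 2) mm
    steps: list[StepRecord]
    geometric_nonlinearity: bool
    load: LoadCase | UniformPressure | None

    @property
    def mesh(self) -> PlanarMesh:
        return self.qmesh.base

    def displacement_at(self, node: int) -> np.ndarray:
        return self.u[node]


# ---------------------------------------------------------------------------
# quadratic (6-node) mesh
# ---------------------------------------------------------------------------


@dataclass
class QuadraticMesh:
    base: PlanarMesh
    nodes: np.ndarray  # (Nq, 2); first base.n_nodes rows are corner nodes
    elements: np.ndarray  # (M, 6): corners n0 n1 n2, midsides m01 m12 m20
    bedges: np.ndarray  # (B, 3): end, end, midside, CCW domain-on-left
    btags: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def nodes_with_tag(self, tag: str) -> np.ndarray:
        if tag == "__all__":
            return np.unique(self.bedges)
        keep = [i for i, t in enumerate(self.btags) if t == tag]
        return np.unique(self.bedges[keep])


def make_quadratic(mesh: PlanarMesh) -> QuadraticMesh:
    """Insert midside nodes on every unique edge of the triangulation."""
    tri = mesh.triangles
    edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    mid = mesh.nodes[uniq].mean(axis=1)
    nn = mesh.n_nodes
    midx = inv.reshape(3, -1).T + nn  # (M, 3) midside ids for edges 01,12,20
    elements = np.hstack([tri, midx])
    nodes = np.vstack([mesh.nodes, mid])

    # boundary edges, oriented CCW (domain on left) with their midside node
    edge_lookup = {tuple(e): i + nn for i, e in enumerate(map(tuple, uniq))}
    directed = {}
    for e_row in edges:  # direction as traversed by the (CCW) owner triangle
        directed[tuple(e_row)] = True
    b3 = []
    for e in mesh.boundary_edges:
        a, b = int(e[0]), int(e[1])
        if (a, b) not in directed:
            a, b = b, a
        m = edge_lookup[tuple(sorted((a, b)))]
        b3.append((a, b, m))
    return QuadraticMesh(
        base=mesh,
        nodes=nodes,
        elements=elements,
        bedges=np.asarray(b3, dtype=np.int64),
        btags=list(mesh.boundary_tags),
    )


# --- reference-element tables ----------------------------------------------

# interior: 3-point rule at the edge midpoints of the barycentric triangle
_QP = np.array([[0.5, 0.0], [0.5, 0.5], [0.0, 0.5]])
_QW = np.array([1.0 / 3, 1.0 / 3, 1.0 / 3]) * 0.5  # reference triangle area 1/2


def _shape_t6(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    l1, l2, l3 = 1.0 - xi - eta, xi, eta
    N = np.array(
        [
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            l3 * (2 * l3 - 1),
            4 * l1 * l2,
            4 * l2 * l3,
            4 * l3 * l1,
        ]
    )
    d1, d2, d3 = np.array([-1.0, -1.0]), np.array([1.0, 0.0]), np.array([0.0, 1.0])
    dN = np.array(
        [
            (4 * l1 - 1) * d1,
            (4 * l2 - 1) * d2,
            (4 * l3 - 1) * d3,
            4 * (l2 * d1 + l1 * d2),
            4 * (l3 * d2 + l2 * d3),
            4 * (l1 * d3 + l3 * d1),
        ]
    )
    return N, dN  # (6,), (6, 2)


_SHP = [_shape_t6(x, e) for x, e in _QP]

# 3-point Gauss-Legendre on [-1, 1] for boundary edges
_EG = np.array([-math.sqrt(3.0 / 5.0), 0.0, math.sqrt(3.0 / 5.0)])
_EW = np.array([5.0 / 9, 8.0 / 9, 5.0 / 9])


def _edge_shape(xi: float) -> tuple[np.ndarray, np.ndarray]:
    N = np.array([0.5 * xi * (xi - 1.0), 0.5 * xi * (xi + 1.0), 1.0 - xi * xi])
    dN = np.array([xi - 0.5, xi + 0.5, -2.0 * xi])
    return N, dN


_ESHP = [_edge_shape(x) for x in _EG]


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _element_quantities(
    qm: QuadraticMesh,
    u: np.ndarray,
    lam: np.ndarray,
    mu: np.ndarray,
    small_strain: bool,
):
    """Internal force vector, tangent blocks and minimum det(F) per qp."""
    el = qm.elements
    X = qm.nodes[el]  # (M, 6, 2)
    ue = u[el]  # (M, 6, 2)
    M = len(el)
    fint = np.zeros((M, 6, 2))
    K = np.zeros((M, 12, 12))
    D = np.zeros((M, 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = lam + 2 * mu
    D[:, 0, 1] = D[:, 1, 0] = lam
    D[:, 2, 2] = mu
    min_detF = np.inf

    for (N, dN), w in zip(_SHP, _QW):
        J = np.einsum("mai,ag->mig", X, dN)  # (M, 2, 2)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        invJ = np.empty_like(J)
        invJ[:, 0, 0] = J[:, 1, 1]
        invJ[:, 1, 1] = J[:, 0, 0]
        invJ[:, 0, 1] = -J[:, 0, 1]
        invJ[:, 1, 0] = -J[:, 1, 0]
        invJ /= detJ[:, None, None]
        g = np.einsum("ag,mgj->maj", dN, invJ)  # (M, 6, 2) grad N wrt X

        H = np.einsum("mai,maj->mij", ue, g)  # displacement gradient
        if small_strain:
            Estr = 0.5 * (H + H.transpose(0, 2, 1))
            Fb = np.zeros_like(H)
            Fb[:, 0, 0] = Fb[:, 1, 1] = 1.0
            S = np.zeros_like(H)
            trE = Estr[:, 0, 0] + Estr[:, 1, 1]
            S[:, 0, 0] = lam * trE + 2 * mu * Estr[:, 0, 0]
            S[:, 1, 1] = lam * trE + 2 * mu * Estr[:, 1, 1]
            S[:, 0, 1] = S[:, 1, 0] = 2 * mu * Estr[:, 0, 1]
            P = S
            Sgeo = np.zeros_like(S)
        else:
            F = H.copy()
            F[:, 0, 0] += 1.0
            F[:, 1, 1] += 1.0
            detF = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
            min_detF = min(min_detF, float(detF.min()))
            C = np.einsum("mki,mkj->mij", F, F)
            Estr = 0.5 * (C - np.eye(2))
            trE = Estr[:, 0, 0] + Estr[:, 1, 1]
            S = 2 * mu[:, None, None] * Estr
            S[:, 0, 0] += lam * trE
            S[:, 1, 1] += lam * trE
            P = np.einsum("mik,mkj->mij", F, S)
            Fb = F
            Sgeo = S

        wd = w * detJ
        fint += wd[:, None, None] * np.einsum("mij,maj->mai", P, g)

        # strain-displacement matrix B (voigt rows: E11, E22, 2E12)
        B = np.zeros((M, 6, 3, 2))
        B[:, :, 0, 0] = Fb[:, None, 0, 0] * g[:, :, 0]
        B[:, :, 0, 1] = Fb[:, None, 1, 0] * g[:, :, 0]
        B[:, :, 1, 0] = Fb[:, None, 0, 1] * g[:, :, 1]
        B[:, :, 1, 1] = Fb[:, None, 1, 1] * g[:, :, 1]
        B[:, :, 2, 0] = Fb[:, None, 0, 0] * g[:, :, 1] + Fb[:, None, 0, 1] * g[:, :, 0]
        B[:, :, 2, 1] = Fb[:, None, 1, 0] * g[:, :, 1] + Fb[:, None, 1, 1] * g[:, :, 0]

        Kmat = np.einsum("mapi,mpq,mbqk->maibk", B, D, B)
        Kgeo = np.einsum("maj,mjl,mbl->mab", g, Sgeo, g)
        Kq = Kmat + Kgeo[:, :, None, :, None] * np.eye(2)[None, None, :, None, :]
        K += wd[:, None, None] * Kq.reshape(M, 12, 12)

    fglob = np.zeros((qm.n_nodes, 2))
    np.add.at(fglob, el.ravel(), fint.reshape(-1, 2))
    return fglob, K, min_detF


def _scatter(qm: QuadraticMesh, Kel: np.ndarray) -> sp.csr_matrix:
    el = qm.elements
    dof = np.stack([2 * el, 2 * el + 1], axis=2).reshape(len(el), 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 2 * qm.n_nodes
    return sp.coo_matrix((Kel.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def _loaded_edges(qm: QuadraticMesh, load: LoadCase | UniformPressure) -> np.ndarray:
    if isinstance(load, UniformPressure):
        keep = [i for i, t in enumerate(qm.btags) if t == load.edge_tag]
        return qm.bedges[keep]
    base = qm.base
    if base.arc_center is None:
        raise ValueError("sector load requires a mesh with a top arc")
    cx, cy = base.arc_center
    keep = []
    delta = load.support_half_width
    for i, t in enumerate(qm.btags):
        if t != "top_arc":
            continue
        e = qm.bedges[i]
        mx, my = qm.nodes[e[2]]
        th = math.degrees(math.atan2(my - cy, mx - cx))
        if abs(th - load.sector_center_angle) < delta + 1e-9:
            keep.append(i)
    return qm.bedges[np.array(keep, dtype=int)] if keep else np.empty((0, 3), int)


def _external_load(
    qm: QuadraticMesh,
    edges: np.ndarray,
    load: LoadCase | UniformPressure,
    u: np.ndarray,
    factor: float,
    follower: bool,
) -> tuple[np.ndarray, sp.csr_matrix | None]:
    """Consistent nodal forces of the pressure (and its load stiffness)."""
    n = 2 * qm.n_nodes
    f = np.zeros((qm.n_nodes, 2))
    if len(edges) == 0:
        return f, None
    Xr = qm.nodes[edges]  # (B, 3, 2) reference
    xc = Xr + (u[edges] if follower else 0.0)
    rows, cols, vals = [], [], []
    cx, cy = (qm.base.arc_center or (0.0, 0.0))
    for (N, dN), w in zip(_ESHP, _EW):
        xref = np.einsum("a,bai->bi", N, Xr)
        if isinstance(load, UniformPressure):
            p = np.full(len(edges), load.pressure)
        else:
            th = np.degrees(np.arctan2(xref[:, 1] - cy, xref[:, 0] - cx))
            p = sector_pressure(th, load)
        p = p * factor
        tau = np.einsum("a,bai->bi", dN, xc)  # (B, 2) tangent * jacobian
        # outward normal (CCW traversal): (tau_y, -tau_x)
        contrib = np.empty((len(edges), 3, 2))
        contrib[:, :, 0] = -(w * p * tau[:, 1])[:, None] * N[None, :]
        contrib[:, :, 1] = (w * p * tau[:, 0])[:, None] * N[None, :]
        np.add.at(f, edges.ravel(), contrib.reshape(-1, 2))
        if follower:
            # d f_a,x / d u_b,y = -w p N_a dN_b ; d f_a,y / d u_b,x = +w p N_a dN_b
            for a in range(3):
                for b in range(3):
                    c = w * p * N[a] * dN[b]
                    rows.append(2 * edges[:, a])
                    cols.append(2 * edges[:, b] + 1)
                    vals.append(-c)
                    rows.append(2 * edges[:, a] + 1)
                    cols.append(2 * edges[:, b])
                    vals.append(c)
    Kext = None
    if follower and rows:
        Kext = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
    return f, Kext


def _dirichlet_dofs(
    qm: QuadraticMesh, bc: BoundaryConditions
) -> tuple[np.ndarray, np.ndarray]:
    """Constrained dof indices and their (full-load) values."""
    dofs: list[int] = []
    vals: list[float] = []
    for d in bc.dirichlet:
        nodes = qm.nodes_with_tag(d.tag)
        x, y = qm.nodes[nodes, 0], qm.nodes[nodes, 1]
        v = d.value(x, y) if callable(d.value) else np.full(len(nodes), d.value)
        dofs.extend(2 * nodes + d.component)
        vals.extend(np.asarray(v, dtype=float))
    for node, comp in bc.pin_nodes:
        dofs.append(2 * node + comp)
        vals.append(0.0)
    dofs_a = np.asarray(dofs, dtype=np.int64)
    vals_a = np.asarray(vals, dtype=float)
    uniq, first = np.unique(dofs_a, return_index=True)
    return uniq, vals_a[first]


def assemble_and_solve(
    mesh: PlanarMesh | QuadraticMesh,
    materials: MaterialMap,
    bc: BoundaryConditions,
    load: LoadCase | UniformPressure | None,
    opts: SolverOptions = SolverOptions(),
) -> Solution:
    """Solve the (in)finite-strain equilibrium problem by Newton stepping.

    The load (pressure amplitude and prescribed boundary displacements) is
    ramped in equal increments; each step is solved by full Newton with the
    consistent tangent (including the follower-pressure load stiffness).
    Divergence triggers automatic step halving, up to ``opts.max_halvings``
    times, before a :class:`NonConvergenceError` is raised.
    """
    qm = mesh if isinstance(mesh, QuadraticMesh) else make_quadratic(mesh)
    lam, mu = materials.lame_arrays(qm.base)
    fix_dofs, fix_vals = _dirichlet_dofs(qm, bc)
    n = 2 * qm.n_nodes
    free = np.setdiff1d(np.arange(n), fix_dofs)

    follower = bool(load is not None and getattr(load, "follower", False))
    edges = _loaded_edges(qm, load) if load is not None else np.empty((0, 3), int)

    n_steps = opts.n_steps
    if n_steps is None and load is not None and load.n_steps is not None:
        n_steps = load.n_steps
    if n_steps is None:
        peak = load.peak_pressure if load is not None else 0.0
        softest = min(m.E for m in materials.values())
        n_steps = 1 if opts.small_strain else max(1, math.ceil(10.0 * peak / (0.5 * softest)))
        n_steps = min(n_steps, 10)

    u = np.zeros((qm.n_nodes, 2))
    steps: list[StepRecord] = []
    frac = 0.0
    dfrac = 1.0 / n_steps
    halvings = 0

    def _residual(u_state: np.ndarray, factor: float):
        fint, Kel, min_detF = _element_quantities(
            qm, u_state, lam, mu, opts.small_strain
        )
        fext, Kext = _external_load(qm, edges, load, u_state, factor, follower)
        r = (fint - fext).reshape(-1)
        return float(np.linalg.norm(r[free])), r, Kel, Kext, min_detF

    atol = 1e-14 * max(1.0, float(np.abs(lam).max()))

    while frac < 1.0 - 1e-12:
        target = min(1.0, frac + dfrac)
        u_trial = u.copy()
        u_flat = u_trial.reshape(-1)
        u_flat[fix_dofs] = fix_vals * target
        residuals: list[float] = []
        converged = False
        rn, r, Kel, Kext, min_detF = _residual(u_trial, target)
        r0 = max(rn, 1e-300)
        residuals.append(rn)
        for it in range(opts.max_iterations):
            if rn <= opts.tolerance * r0 or rn < atol:
                converged = True
                break
            K = _scatter(qm, Kel)
            if Kext is not None:
                K = K - Kext
            Kff = K[free][:, free].tocsc()
            try:
                du = spla.splu(Kff).solve(-r[free])
            except RuntimeError as exc:
                raise NonConvergenceError(f"linear solve failed: {exc}", frac)
            # backtracking line search on the residual norm
            alpha = 1.0
            accepted = False
            for _ in range(opts.max_line_search):
                u_new = u_flat.copy()
                u_new[free] += alpha * du
                if np.all(np.isfinite(u_new)):
                    rn_n, r_n, Kel_n, Kext_n, md_n = _residual(
                        u_new.reshape(-1, 2), target
                    )
                    if rn_n < (1.0 - 1e-4 * alpha) * rn or rn_n < atol:
                        u_flat[:] = u_new
                        rn, r, Kel, Kext, min_detF = rn_n, r_n, Kel_n, Kext_n, md_n
                        accepted = True
                        break
                alpha *= 0.5
            residuals.append(rn)
            if not accepted:
                break
        if converged and not opts.small_strain and min_detF <= 0.0:
            # the equilibrium state itself is inverted: not a valid solution
            raise NonConvergenceError(
                f"inverted element in converged state at load fraction {target:.3g}",
                frac,
            )
        if converged:
            u = u_trial
            frac = target
            steps.append(StepRecord(frac, len(residuals), residuals))
            logger.debug(
                "load fraction %.3g converged in %d iterations (resid %.3e)",
                frac,
                len(residuals),
                residuals[-1] if residuals else 0.0,
            )
        else:
            halvings += 1
            if halvings > opts.max_halvings:
                raise NonConvergenceError(
                    f"Newton iteration did not converge at load fraction "
                    f"{target:.3g} after {opts.max_halvings} step halvings",
                    frac,
                )
            dfrac *= 0.5
            logger.info("halving load step to %.3g at fraction %.3g", dfrac, frac)

    return Solution(
        qmesh=qm,
        u=u,
        steps=steps,
        geometric_nonlinearity=not opts.small_strain,
        load=load,
    )
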