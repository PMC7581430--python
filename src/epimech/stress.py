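"""Second Piola–Kirchhoff stress recovery and scalar stress measures.

Stresses are evaluated per element (quadrature average reported at the
reference centroid, with no nodal smoothing, so zone peaks are not diluted
across material interfaces) and reduced to the three scalar measures used
to characterize the loading state of growth-plate chondrocytes:

* hydrostatic stress σ_h = (s₁+s₂+s₃)/3 — the shape-preserving pressure;
* the lowest principal stress s₃ — the dominant compressive direction;
* octahedral shear stress τ_oct = ⅓√((s₁−s₂)²+(s₂−s₃)²+(s₃−s₁)²) — the
  shape-distorting component, equal to √(2J₂/3).

Plane strain makes the out-of-plane stress S33 = λ(E11+E22) nonzero; all
measures use the full 3D tensor.  Because the stress states of interest
are compression-dominated, plotting conventions flip the sign of the first
two measures; computation never does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fem import MaterialMap, Solution, _SHP, _QW
from .geometry import PlanarMesh, SubdomainLabel

logger = logging.getLogger(__name__)

__all__ = [
    "StressTensorField",
    "ScalarStressField",
    "ZoneSummary",
    "second_pk_stress",
    "principal_stresses",
    "octahedral_shear",
    "hydrostatic",
    "scalar_measures",
    "zone_summary",
    "deflection",
    "deformed_coordinates",
]


@dataclass
class StressTensorField:
    """Per-element 2nd Piola–Kirchhoff stress (MPa), plane-strain S33."""

    S11: np.ndarray
    S22: np.ndarray
    S12: np.ndarray
    S33: np.ndarray
    centroids: np.ndarray  # (M, 2) reference configuration

    def as_tensors(self) -> np.ndarray:
        """(M, 3, 3) symmetric tensors with S13 = S23 = 0."""
        M = len(self.S11)
        S = np.zeros((M, 3, 3))
        S[:, 0, 0] = self.S11
        S[:, 1, 1] = self.S22
        S[:, 0, 1] = S[:, 1, 0] = self.S12
        S[:, 2, 2] = self.S33
        return S


@dataclass
class ScalarStressField:
    """Principal triple and derived scalar measures per element (MPa)."""

    s1: np.ndarray  # largest principal
    s2: np.ndarray
    s3: np.ndarray  # lowest principal ("always compressive" in the models)
    hydrostatic: np.ndarray
    tau_oct: np.ndarray

    def plotting(self, measure: str) -> np.ndarray:
        """Figure conventions: sign of σ_h and s₃ flipped, τ_oct as-is."""
        if measure == "hydrostatic":
            return -self.hydrostatic
        if measure == "min_principal":
            return -self.s3
        if measure == "tau_oct":
            return self.tau_oct
        raise KeyError(measure)


def second_pk_stress(
    sol: Solution, mesh: PlanarMesh, materials: MaterialMap
) -> StressTensorField:
    """S = λ tr(E) I + 2μ E from the Green–Lagrange strain of a solution.

    In the small-strain case the engineering strain replaces E (the measure
    the solution was computed with).  Values are quadrature averages.
    """
    qm = sol.qmesh
    if qm.base is not mesh and qm.base.n_elements != mesh.n_elements:
        raise ValueError("solution and mesh element counts do not match")
    lam, mu = materials.lame_arrays(qm.base)
    el = qm.elements
    X = qm.nodes[el]
    ue = sol.u[el]
    M = len(el)
    acc = np.zeros((M, 4))  # S11 S22 S12 trE
    wsum = 0.0
    for (N, dN), w in zip(_SHP, _QW):
        J = np.einsum("mai,ag->mig", X, dN)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        invJ = np.empty_like(J)
        invJ[:, 0, 0] = J[:, 1, 1]
        invJ[:, 1, 1] = J[:, 0, 0]
        invJ[:, 0, 1] = -J[:, 0, 1]
        invJ[:, 1, 0] = -J[:, 1, 0]
        invJ /= detJ[:, None, None]
        g = np.einsum("ag,mgj->maj", dN, invJ)
        H = np.einsum("mai,maj->mij", ue, g)
        if sol.geometric_nonlinearity:
            F = H.copy()
            F[:, 0, 0] += 1.0
            F[:, 1, 1] += 1.0
            C = np.einsum("mki,mkj->mij", F, F)
            E = 0.5 * (C - np.eye(2))
        else:
            E = 0.5 * (H + H.transpose(0, 2, 1))
        trE = E[:, 0, 0] + E[:, 1, 1]
        acc[:, 0] += w * (lam * trE + 2 * mu * E[:, 0, 0])
        acc[:, 1] += w * (lam * trE + 2 * mu * E[:, 1, 1])
        acc[:, 2] += w * (2 * mu * E[:, 0, 1])
        acc[:, 3] += w * trE
        wsum += w
    acc /= wsum
    return StressTensorField(
        S11=acc[:, 0],
        S22=acc[:, 1],
        S12=acc[:, 2],
        S33=lam * acc[:, 3],
        centroids=qm.base.centroids(),
    )


def principal_stresses(
    S11: np.ndarray | float,
    S22: np.ndarray | float,
    S12: np.ndarray | float,
    S33: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sorted principal stresses s₁ ≥ s₂ ≥ s₃ of [[S11,S12,0],[S12,S22,0],[0,0,S33]].

    The in-plane pair comes from the 2×2 closed form; the third eigenvalue
    is S33 itself.
    """
    S11, S22, S12, S33 = np.broadcast_arrays(
        np.asarray(S11, float), np.asarray(S22, float), S12, S33
    )
    m = 0.5 * (S11 + S22)
    r = np.sqrt((0.5 * (S11 - S22)) ** 2 + np.asarray(S12, float) ** 2)
    trio = np.stack([m + r, m - r, np.asarray(S33, float)], axis=-1)
    trio = np.sort(trio, axis=-1)[..., ::-1]
    return trio[..., 0], trio[..., 1], trio[..., 2]


def octahedral_shear(s1, s2, s3) -> np.ndarray:
    """τ_oct = ⅓ √((s₁−s₂)² + (s₂−s₃)² + (s₃−s₁)²)."""
    s1, s2, s3 = np.asarray(s1, float), np.asarray(s2, float), np.asarray(s3, float)
    return np.sqrt((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2) / 3.0


def hydrostatic(s1, s2, s3, *, plotting: bool = False) -> np.ndarray:
    """Mean stress (s₁+s₂+s₃)/3; ``plotting=True`` flips the sign."""
    h = (np.asarray(s1, float) + s2 + s3) / 3.0
    return -h if plotting else h


def scalar_measures(field: StressTensorField) -> ScalarStressField:
    s1, s2, s3 = principal_stresses(field.S11, field.S22, field.S12, field.S33)
    if np.any(s3 > 0):
        logger.info(
            "tensile lowest principal stress in %d elements (max %.3g MPa); "
            "reported unclamped",
            int(np.sum(s3 > 0)),
            float(s3.max()),
        )
    return ScalarStressField(
        s1=s1,
        s2=s2,
        s3=s3,
        hydrostatic=hydrostatic(s1, s2, s3),
        tau_oct=octahedral_shear(s1, s2, s3),
    )


@dataclass
class ZoneSummary:
    zone: str
    n_elements: int
    peak: dict[str, float]  # per measure
    mean: dict[str, float]  # area-weighted

    def empty(self) -> bool:
        return self.n_elements == 0


_MEASURES = ("tau_oct", "hydrostatic_compressive", "min_principal_compressive")


def _measure_values(scalars: ScalarStressField, measure: str) -> np.ndarray:
    if measure == "tau_oct":
        return scalars.tau_oct
    if measure == "hydrostatic_compressive":
        return -scalars.hydrostatic
    if measure == "min_principal_compressive":
        return -scalars.s3
    raise KeyError(measure)


def zone_summary(
    scalars: ScalarStressField,
    mesh: PlanarMesh,
    elements: np.ndarray,
    zone: str = "zone",
) -> ZoneSummary:
    """Peak and area-weighted mean of each measure over an element set.

    Compressive measures are summarized on the plotting (sign-flipped)
    convention, so "peak" means the strongest compression.
    """
    elements = np.asarray(elements, dtype=int)
    if len(elements) == 0:
        logger.warning("zone summary over empty zone %r", zone)
        return ZoneSummary(zone=zone, n_elements=0, peak={}, mean={})
    areas = mesh.areas()[elements]
    peak = {}
    mean = {}
    for m in _MEASURES:
        v = _measure_values(scalars, m)[elements]
        peak[m] = float(v.max())
        mean[m] = float(np.average(v, weights=areas))
    return ZoneSummary(zone=zone, n_elements=len(elements), peak=peak, mean=mean)


def deflection(sol: Solution, mesh: PlanarMesh, lc) -> float:
    """Displacement magnitude at the top-arc node nearest the load-sector
    center (the visually reported "level of deflection")."""
    angles = mesh.arc_angles()
    if not angles:
        raise ValueError("mesh has no tagged top arc")
    center = getattr(lc, "sector_center_angle", 90.0)
    node = min(angles, key=lambda n: abs(angles[n] - center))
    return float(np.linalg.norm(sol.u[node]))


def deformed_coordinates(mesh_or_sol, sol: Solution | None = None) -> np.ndarray:
    """Deformed node coordinates x = X + u, unmagnified (scale exactly 1).

    Accepts ``(mesh, sol)`` (returns corner-node coordinates) or a solution
    alone (returns all quadratic-node coordinates).
    """
    if sol is None:
        sol = mesh_or_sol
        return sol.qmesh.nodes + sol.u
    mesh: PlanarMesh = mesh_or_sol
    return mesh.nodes + sol.u[: mesh.n_nodes]
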