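"""Synthetic fixtures with known ground truth.

The study's raw instrument recordings (AFM/nanoindenter force curves,
materials-testing load–deformation records) are not published, so every
analysis routine is validated on generated data whose true parameters are
known and embedded in the returned object's metadata.  All generators are
deterministic functions of their arguments and a seed.

What is emulated: Hertzian contact with additive Gaussian force noise;
linear-then-softening structural response sampled at the study's 0.1 N/s
load rate with Gaussian position noise; homogeneous blocks with
closed-form plane-strain solutions; random plane-strain stress tensors
with brute-force eigendecompositions.  What is not: instrument artifacts
such as piezo hysteresis, thermal drift or cantilever tilt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fem import (
    BoundaryConditions,
    DirichletBC,
    Material,
    MaterialMap,
    UniformPressure,
)
from .geometry import PlanarMesh, SubdomainLabel
from .hertz import AFM_PRESET, NANOINDENTER_PRESET, ForceDistanceCurve, hertz_force
from .mechtest import EpiphysisDims, LoadDeformationRecord

__all__ = [
    "gen_force_curves",
    "gen_load_deformation",
    "rectangle_mesh",
    "gen_block_fixture",
    "BlockFixture",
    "gen_stress_tensors",
]


def gen_force_curves(
    E_true_kPa: float,
    z0_um: float,
    noise_sd: float,
    n: int,
    instrument: str = "afm",
    seed: int = 0,
    nu: float = 0.5,
    n_samples: int = 400,
) -> list[ForceDistanceCurve]:
    """Generate force–distance curves from a known Hertzian sample.

    ``noise_sd`` is the additive Gaussian force noise as a fraction of the
    curve's maximum force.  The AFM preset draws the spring constant from
    the study's 0.06–0.09 N/m range and indents to 10 % of the 5 µm tip
    radius; the nanoindenter preset (k = 4.14 N/m, R = 45.5 µm) immerses
    the probe 5 µm.  Ground truth is stored in each curve's metadata.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if E_true_kPa <= 0 or z0_um < 0:
        raise ValueError("parameters must be physical")
    rng = np.random.default_rng(seed)
    preset = AFM_PRESET if instrument == "afm" else NANOINDENTER_PRESET
    R = preset.tip_radius_um
    dmax = preset.max_indentation_um

    curves = []
    for _ in range(n):
        k = (
            rng.uniform(0.06, 0.09)
            if instrument == "afm"
            else preset.spring_constant_N_per_m
        )
        # piezo ramp: baseline approach then contact to maximum indentation
        if instrument == "afm":
            # solve k d = hertz(z - z0 - d) on a z grid (Newton on d)
            zmax_guess = z0_um + dmax * 2.0
            z = np.linspace(z0_um - 1.0, zmax_guess, n_samples)
            d = np.zeros_like(z)
            for _ in range(60):
                delta = np.maximum(z - z0_um - d, 0.0)
                f = hertz_force(delta, E_true_kPa, nu, R)
                # F = k*d with d in nm -> k*d [nN] when d in nm: use µm*1e3
                g = k * (d * 1e3) - f
                dg = k * 1e3 + 1.5 * f / np.maximum(delta, 1e-12) * (delta > 0)
                d = d - g / dg
                d = np.maximum(d, 0.0)
            delta = np.maximum(z - z0_um - d, 0.0)
            scale = np.max(delta) / dmax
            # rescale ramp end so max indentation hits the preset depth
            z = z0_um - 1.0 + (z - (z0_um - 1.0)) / max(scale, 1e-9)
            d = np.zeros_like(z)
            for _ in range(60):
                delta = np.maximum(z - z0_um - d, 0.0)
                f = hertz_force(delta, E_true_kPa, nu, R)
                g = k * (d * 1e3) - f
                dg = k * 1e3 + 1.5 * f / np.maximum(delta, 1e-12) * (delta > 0)
                d = np.maximum(d - g / dg, 0.0)
            F = k * (d * 1e3)
            noise = rng.normal(0.0, noise_sd * max(F.max(), 1e-12), size=F.shape)
            Fn = F + noise
            curve = ForceDistanceCurve(
                z_um=z,
                deflection_nm=Fn / k,
                spring_constant_N_per_m=k,
                tip_radius_um=R,
                direction="retract",
                instrument="afm",
            )
        else:
            z = np.linspace(z0_um - 1.0, z0_um + dmax, n_samples)
            delta = np.maximum(z - z0_um, 0.0)
            F = hertz_force(delta, E_true_kPa, nu, R)
            noise = rng.normal(0.0, noise_sd * max(F.max(), 1e-12), size=F.shape)
            curve = ForceDistanceCurve(
                z_um=z,
                force_nN=F + noise,
                spring_constant_N_per_m=k,
                tip_radius_um=R,
                direction="approach",
                instrument="nanoindenter",
            )
        curve.metadata.update(
            {
                "E_true_kPa": E_true_kPa,
                "z0_true_um": z0_um,
                "nu": nu,
                "noise_sd": noise_sd,
                "seed": seed,
            }
        )
        curves.append(curve)
    return curves


def gen_load_deformation(
    stiffness_true: float,
    yield_stress_true: float,
    dims: EpiphysisDims,
    noise_sd: float = 0.01,
    seed: int = 0,
    orientation: str = "vertical",
    max_load_factor: float = 1.5,
    sample_dt_s: float = 0.1,
    post_yield_fraction: float = 0.2,
) -> LoadDeformationRecord:
    """Bilinear load–deformation record with known structural parameters.

    The elastic branch has slope ``stiffness_true`` (N/mm) up to the knee
    where the nominal stress on the loaded oval reaches
    ``yield_stress_true`` (MPa); beyond it the tangent drops to 20 % of the
    elastic slope (a documented convention for recovery testing only).
    The machine ramps load at 0.1 N/s; Gaussian noise (``noise_sd`` of the
    full position range) is added to positions.  Metadata carries the
    generator truth plus the closed-form 0.2 %-offset yield stress implied
    by the bilinear curve.
    """
    if stiffness_true <= 0 or yield_stress_true <= 0:
        raise ValueError("parameters must be positive")
    d1, d2 = dims.diameters(orientation)
    area = math.pi * (d1 / 2.0) * (d2 / 2.0)
    F_knee = yield_stress_true * area
    x_knee = F_knee / stiffness_true
    k2 = post_yield_fraction * stiffness_true
    rate = 0.1  # N/s

    F_max = max_load_factor * F_knee
    t = np.arange(0.0, F_max / rate + sample_dt_s, sample_dt_s)
    F = rate * t
    x = np.where(F <= F_knee, F / stiffness_true, x_knee + (F - F_knee) / k2)
    # pre-contact approach segment at zero load
    n_pre = 8
    x_pre = np.linspace(-0.05 * x.max(), 0.0, n_pre, endpoint=False)
    F_full = np.concatenate([np.zeros(n_pre), F])
    x_full = np.concatenate([x_pre, x]) + 0.123  # arbitrary fixture offset

    rng = np.random.default_rng(seed)
    x_noisy = x_full + rng.normal(0.0, noise_sd * np.ptp(x_full), size=x_full.shape)

    # closed-form 0.2%-offset yield on the noiseless bilinear stress-strain
    E0 = stiffness_true * dims.height / area  # MPa
    eps_knee = x_knee / dims.height
    E2 = post_yield_fraction * E0
    offset = 0.002
    eps_y = (yield_stress_true - E2 * eps_knee + E0 * offset) / (E0 - E2)
    sigma_y = E0 * (eps_y - offset)

    rec = LoadDeformationRecord(
        position_mm=x_noisy,
        load_N=F_full,
        load_rate_N_per_s=rate,
        orientation=orientation,
        specimen_id=f"synthetic-{seed}",
    )
    rec.metadata.update(
        {
            "stiffness_true_N_per_mm": stiffness_true,
            "knee_stress_MPa": yield_stress_true,
            "offset_yield_true_MPa": float(sigma_y),
            "initial_modulus_true_MPa": float(E0),
            "noise_sd": noise_sd,
            "seed": seed,
            "contact_index_true": n_pre,
        }
    )
    return rec


def rectangle_mesh(
    width: float, height: float, nx: int, ny: int,
    label: SubdomainLabel = SubdomainLabel.EPIPHYSEAL_CARTILAGE,
) -> PlanarMesh:
    """Structured crossed-diagonal triangulation of a rectangle.

    Boundary tags: bottom / top / left / right.
    """
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b, c, d = nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
            else:
                tris += [[a, b, d], [b, c, d]]
    edges, tags = [], []
    for i in range(nx):
        edges.append([nid(i, 0), nid(i + 1, 0)])
        tags.append("bottom")
        edges.append([nid(i + 1, ny), nid(i, ny)])
        tags.append("top")
    for j in range(ny):
        edges.append([nid(nx, j), nid(nx, j + 1)])
        tags.append("right")
        edges.append([nid(0, j + 1), nid(0, j)])
        tags.append("left")
    idx = list(SubdomainLabel).index(label)
    return PlanarMesh(
        nodes=nodes,
        triangles=np.asarray(tris),
        labels=np.full(len(tris), idx, dtype=np.int64),
        label_order=list(SubdomainLabel),
        boundary_edges=np.asarray(edges),
        boundary_tags=tags,
    )


@dataclass
class BlockFixture:
    """Homogeneous block with its plane-strain closed-form solution."""

    mesh: PlanarMesh
    materials: MaterialMap
    bc: BoundaryConditions
    load: UniformPressure
    u_top_analytic: float  # mm
    sigma_xx: float
    sigma_yy: float
    sigma_zz: float


def gen_block_fixture(
    width: float = 10.0,
    height: float = 10.0,
    E: float = 6.0,
    nu: float = 0.47,
    p: float = 0.01,
    target_h: float = 2.0,
) -> BlockFixture:
    """Verification oracle: rollers at the bottom (one node pinned
    horizontally), free sides, uniform top pressure.

    The exact plane-strain state is uniform: σ_yy = −p, σ_xx = 0,
    σ_zz = −νp, and the top edge moves by u = −p·h·(1−ν²)/E.
    """
    if min(width, height, E, target_h) <= 0 or not 0 <= nu < 0.5:
        raise ValueError("parameters must be positive with nu < 0.5")
    nx = max(2, round(width / target_h))
    ny = max(2, round(height / target_h))
    mesh = rectangle_mesh(width, height, nx, ny)
    mat = MaterialMap({lab: Material(E, nu) for lab in SubdomainLabel})
    bc = BoundaryConditions(
        dirichlet=(DirichletBC("bottom", 1, 0.0),), pin_nodes=((0, 0),)
    )
    load = UniformPressure(pressure=p, edge_tag="top")
    u_top = -p * height * (1.0 - nu**2) / E
    return BlockFixture(
        mesh=mesh,
        materials=mat,
        bc=bc,
        load=load,
        u_top_analytic=u_top,
        sigma_xx=0.0,
        sigma_yy=-p,
        sigma_zz=-nu * p,
    )


def gen_stress_tensors(
    n: int, scale: float = 1.0, seed: int = 0
) -> list[dict]:
    """Random symmetric plane-strain-type tensors with oracle records.

    Each entry holds the tensor components (S13 = S23 = 0) together with
    principal stresses from a generic eigensolver and scalar measures
    computed from tensor invariants (hydrostatic from the trace, τ_oct
    from the deviatoric second invariant J₂), independent of the
    closed-form routines they are used to check.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        s11, s22, s12, s33 = rng.normal(0.0, 1.0, 4) * scale
        S = np.array([[s11, s12, 0.0], [s12, s22, 0.0], [0.0, 0.0, s33]])
        ev = np.linalg.eigvalsh(S)[::-1]
        tr = np.trace(S)
        dev = S - tr / 3.0 * np.eye(3)
        J2 = 0.5 * float(np.sum(dev * dev))
        out.append(
            {
                "S11": s11,
                "S22": s22,
                "S12": s12,
                "S33": s33,
                "principal": ev,
                "hydrostatic": tr / 3.0,
                "tau_oct": math.sqrt(2.0 * J2 / 3.0),
            }
        )
    return out
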