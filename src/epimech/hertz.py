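"""Hertzian contact analysis of AFM and nanoindenter force curves.

A spherical probe of radius R on a flexible cantilever (spring constant k)
is driven into a soft sample.  For the AFM the recorded pair is (piezo
height z, cantilever deflection d): the force is F = k·d and the sample
indentation is δ = (z − z₀) − d, with z₀ the contact point.  A
displacement-controlled nanoindenter reports probe indentation directly,
δ = z − z₀.  The Hertz model for a rigid sphere on an elastic half-space,

    F = (4/3) · E/(1−ν²) · √R · δ^{3/2},

is fitted to the contact region with the modulus and the contact point
(optionally a force baseline) as joint free parameters — joint fitting
because threshold-based contact-point detection dominates the error budget
on soft samples.  Units: µm, nN, kPa (1 kPa = 1 nN/µm², so the formula
needs no conversion factors).

Instrument presets follow the study hardware: AFM with a 5 µm borosilicate
sphere and k = 0.06–0.09 N/m (fits restricted to δ ≤ 0.1·R); nanoindenter
with k = 4.14 N/m, R = 45.5 µm and 5 µm immersion depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "ForceDistanceCurve",
    "IndentationCurve",
    "HertzFit",
    "FitOptions",
    "AFM_PRESET",
    "NANOINDENTER_PRESET",
    "hertz_force",
    "to_indentation",
    "fit_hertz",
    "aggregate",
]


@dataclass(frozen=True)
class InstrumentPreset:
    instrument: str
    spring_constant_N_per_m: float
    tip_radius_um: float
    max_indentation_um: float


AFM_PRESET = InstrumentPreset("afm", 0.075, 5.0, 0.5)  # δ_max = 10% of R
NANOINDENTER_PRESET = InstrumentPreset("nanoindenter", 4.14, 45.5, 5.0)


@dataclass
class ForceDistanceCurve:
    """Raw force–distance recording.

    Exactly one of ``deflection_nm`` / ``force_nN`` is required; deflection
    implies force via F = k·d (k in N/m, d in nm gives F in nN).
    """

    z_um: np.ndarray
    spring_constant_N_per_m: float
    tip_radius_um: float
    deflection_nm: np.ndarray | None = None
    force_nN: np.ndarray | None = None
    direction: str = "retract"  # or "approach"
    instrument: str = "afm"  # or "nanoindenter"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        if self.spring_constant_N_per_m <= 0:
            raise ValueError("spring constant must be > 0")
        if self.tip_radius_um <= 0:
            raise ValueError("tip radius must be > 0")
        if (self.deflection_nm is None) == (self.force_nN is None):
            raise ValueError("exactly one of deflection/force must be given")
        if self.deflection_nm is not None:
            self.deflection_nm = np.asarray(self.deflection_nm, dtype=float)
        if self.force_nN is not None:
            self.force_nN = np.asarray(self.force_nN, dtype=float)
        dz = np.diff(self.z_um)
        if len(dz) and not (np.all(dz >= 0) or np.all(dz <= 0)):
            raise ValueError("z must be monotone within a direction")

    @property
    def force(self) -> np.ndarray:
        """Force in nN (k [N/m] × d [nm] = [nN])."""
        if self.force_nN is not None:
            return self.force_nN
        return self.spring_constant_N_per_m * self.deflection_nm

    @property
    def deflection_um(self) -> np.ndarray:
        if self.deflection_nm is not None:
            return self.deflection_nm * 1e-3
        # nanoindenter-style: treat reported force as already tip-referenced
        return self.force_nN / self.spring_constant_N_per_m * 1e-3


@dataclass
class IndentationCurve:
    indentation_um: np.ndarray
    force_nN: np.ndarray
    contact_point_um: float


def hertz_force(
    delta_um: np.ndarray | float,
    E_kPa: float,
    nu: float,
    R_um: float,
) -> np.ndarray:
    """Hertz sphere-on-half-space force (nN); zero for δ ≤ 0.

    ν may be up to 0.5 inclusive (incompressible cells).
    """
    if R_um <= 0:
        raise ValueError("tip radius must be > 0")
    if E_kPa <= 0:
        raise ValueError("modulus must be > 0")
    if not 0.0 <= nu <= 0.5:
        raise ValueError("Poisson ratio must be in [0, 0.5]")
    d = np.maximum(np.asarray(delta_um, dtype=float), 0.0)
    return (4.0 / 3.0) * (E_kPa / (1.0 - nu**2)) * np.sqrt(R_um) * d**1.5


def to_indentation(curve: ForceDistanceCurve, z0_um: float) -> IndentationCurve:
    """Convert a raw recording to (indentation, force) given a contact point.

    AFM kinematics subtract the cantilever deflection from the piezo
    travel; a nanoindenter already reports probe indentation.
    """
    F = curve.force
    if curve.instrument == "afm":
        if curve.deflection_nm is None:
            d_um = F / curve.spring_constant_N_per_m * 1e-3
        else:
            d_um = curve.deflection_nm * 1e-3
        delta = (curve.z_um - z0_um) - d_um
    else:
        delta = curve.z_um - z0_um
    return IndentationCurve(
        indentation_um=delta, force_nN=F, contact_point_um=z0_um
    )


@dataclass(frozen=True)
class FitOptions:
    max_indentation_um: float | None = None  # default: 10% R (afm) / 5 µm (nano)
    fit_baseline: bool = False
    exclude_adhesion: bool = True  # drop F < 0 samples (retract adhesion well)
    E_bounds_kPa: tuple[float, float] = (1e-3, 1e6)


@dataclass
class HertzFit:
    E_kPa: float
    nu: float
    z0_um: float
    baseline_nN: float
    residual_rms_nN: float
    valid: bool
    message: str = ""


def fit_hertz(
    curve: ForceDistanceCurve,
    nu: float = 0.5,
    opts: FitOptions = FitOptions(),
) -> HertzFit:
    """Jointly fit (E, z₀[, baseline]) by least squares on the force.

    The Poisson ratio is assumed, not fitted (default 0.5, incompressible);
    the returned modulus is the effective Young's modulus under that
    assumption.  Nonconvergence or a modulus at its bound yields a fit
    flagged invalid rather than an exception.
    """
    F = curve.force
    z = curve.z_um
    if len(z) < 50:
        raise ValueError("curve must have at least 50 samples")
    max_delta = opts.max_indentation_um
    if max_delta is None:
        max_delta = (
            0.1 * curve.tip_radius_um if curve.instrument == "afm" else 5.0
        )

    Fmax = float(F.max())
    if Fmax <= 0:
        return HertzFit(np.nan, nu, np.nan, 0.0, np.inf, False, "no positive force")
    # initial contact point: first crossing of 2% peak force
    i0 = int(np.argmax(F > 0.02 * Fmax))
    z0_init = float(z[i0])
    # initial modulus from the deepest point
    ind = to_indentation(curve, z0_init)
    dmax = float(np.max(ind.indentation_um))
    E_init = 10.0
    if dmax > 0:
        E_init = Fmax / max(
            hertz_force(min(dmax, max_delta), 1.0, nu, curve.tip_radius_um), 1e-12
        )
    E_init = float(np.clip(E_init, *opts.E_bounds_kPa))

    mask = np.ones(len(z), dtype=bool)
    if opts.exclude_adhesion:
        mask = F >= 0.0
    zf, Ff = z[mask], F[mask]
    if curve.instrument == "afm":
        d_um = (
            curve.deflection_nm * 1e-3
            if curve.deflection_nm is not None
            else F / curve.spring_constant_N_per_m * 1e-3
        )[mask]
    else:
        d_um = np.zeros(len(zf))

    zspan = float(np.ptp(z)) or 1.0
    lo = [np.log10(opts.E_bounds_kPa[0]), float(z.min()) - 0.5 * zspan]
    hi = [np.log10(opts.E_bounds_kPa[1]), float(z.max()) + 0.5 * zspan]
    x0 = [np.log10(E_init), z0_init]
    if opts.fit_baseline:
        lo.append(-np.inf)
        hi.append(np.inf)
        x0.append(0.0)

    def resid(p):
        logE, z0 = p[0], p[1]
        b = p[2] if opts.fit_baseline else 0.0
        delta = np.minimum((zf - z0) - d_um, max_delta)
        return hertz_force(delta, 10.0**logE, nu, curve.tip_radius_um) + b - Ff

    try:
        res = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-12)
    except Exception as exc:  # pragma: no cover - scipy internal failures
        return HertzFit(np.nan, nu, np.nan, 0.0, np.inf, False, str(exc))

    logE, z0 = res.x[0], res.x[1]
    b = res.x[2] if opts.fit_baseline else 0.0
    E = float(10.0**logE)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    at_bound = (
        logE <= np.log10(opts.E_bounds_kPa[0]) + 1e-6
        or logE >= np.log10(opts.E_bounds_kPa[1]) - 1e-6
    )
    # identifiability: a (near-)rigid surface produces no indentation at
    # the fitted contact point, leaving the modulus unconstrained
    delta_fit = (zf - z0) - d_um
    no_indentation = float(np.max(delta_fit, initial=0.0)) < 1e-3 * max_delta
    poor_fit = rms > 0.2 * Fmax
    valid = bool(res.success and not at_bound and not no_indentation and not poor_fit)
    if at_bound:
        msg = "modulus at bound"
    elif no_indentation:
        msg = "no indentation at fitted contact point (rigid surface?)"
    elif poor_fit:
        msg = f"residual RMS {rms:.3g} exceeds 20% of peak force"
    else:
        msg = "" if valid else res.message
    if not valid:
        logger.info("invalid Hertz fit: %s", msg)
    return HertzFit(E, nu, float(z0), float(b), rms, valid, msg)


def aggregate(
    fits: list[HertzFit],
    scheme: str = "mean_sd",
    units: list | None = None,
):
    """Summarize valid fits.

    ``mean_sd``: (mean, SD, n) over valid fits.  ``median_per_unit``: the
    per-unit medians (robust to the skewed modulus distributions seen in
    tissue) followed by a cross-unit mean/SD; ``units`` assigns each fit to
    a unit (e.g. an animal).
    """
    E = np.array([f.E_kPa for f in fits if f.valid])
    if len(E) == 0:
        raise ValueError("no valid fits to aggregate")
    if scheme == "mean_sd":
        return float(E.mean()), float(E.std(ddof=1)) if len(E) > 1 else 0.0, len(E)
    if scheme == "median_per_unit":
        if units is None:
            raise ValueError("median_per_unit requires unit labels")
        valid_units = [u for f, u in zip(fits, units) if f.valid]
        meds = {}
        for u in sorted(set(valid_units), key=str):
            vals = E[[i for i, uu in enumerate(valid_units) if uu == u]]
            meds[u] = float(np.median(vals))
        m = np.array(list(meds.values()))
        sd = float(m.std(ddof=1)) if len(m) > 1 else 0.0
        return meds, float(m.mean()), sd
    raise ValueError(f"unknown aggregation scheme {scheme!r}")
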