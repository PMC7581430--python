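"""Ex-vivo mechanical-test analysis of whole epiphyses.

A bone epiphysis is compressed at a constant load rate while the machine
records (position, load) samples.  From one such record this module
extracts: the deformation series (position re-referenced to the contact
point), structural stiffness (slope of the initial linear portion of the
load–deformation curve), the stress–strain curve (load spread over the
oval loaded surface, deformation spread over the epiphysis height), and
the 0.2 %-offset yield strength.  It also inverts the stress calculation
to find the load that produces a prescribed pressure on a measured
epiphysis — the pressure-matched loading used to compare bones of
different sizes (e.g. 0.023 MPa ↔ 0.2 N for an early-postnatal rat tibia).

Conventions adopted where the experimental write-up is silent:

* "initial linear portion" = the sliding window (≥ 20 % of samples, and at
  least ``min_window``) confined to the first half of the load range that
  maximizes R², ties broken toward the earliest window;
* deformation is zeroed at first contact, detected as the first sample
  whose load exceeds 2 % of the peak (no machine-compliance correction is
  applied — none is described);
* the oval surface area is the ellipse π·(d₁/2)·(d₂/2) from the two
  caliper diameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MechTestError",
    "NoContactError",
    "NoYieldError",
    "LoadDeformationRecord",
    "EpiphysisDims",
    "StressStrainCurve",
    "MechSummary",
    "StiffnessOptions",
    "deformation_series",
    "stiffness",
    "oval_area",
    "to_stress_strain",
    "offset_yield",
    "load_for_pressure",
    "analyze_record",
]


class MechTestError(ValueError):
    pass


class NoContactError(MechTestError):
    """No sample exceeds the contact threshold."""


class NoYieldError(MechTestError):
    """The offset line never intersects the measured curve."""


@dataclass
class LoadDeformationRecord:
    """Raw machine record: position (mm) and load (N) at a fixed load rate."""

    position_mm: np.ndarray
    load_N: np.ndarray
    load_rate_N_per_s: float = 0.1
    specimen_id: str = ""
    orientation: str = "vertical"  # or "angled"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.load_N = np.asarray(self.load_N, dtype=float)
        if self.position_mm.shape != self.load_N.shape:
            raise MechTestError("position and load must have equal length")
        if len(self.load_N) < 10:
            raise MechTestError("record must contain at least 10 samples")
        if not np.all(np.isfinite(self.position_mm)):
            raise MechTestError("positions must be finite")
        if self.orientation not in ("vertical", "angled"):
            raise MechTestError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class EpiphysisDims:
    """Caliper measurements: height plus top and side surface diameters (mm)."""

    height: float
    top_d1: float
    top_d2: float
    side_e1: float
    side_e2: float

    def __post_init__(self) -> None:
        for name in ("height", "top_d1", "top_d2", "side_e1", "side_e2"):
            if getattr(self, name) <= 0:
                raise MechTestError(f"dimension {name} must be > 0")

    def diameters(self, orientation: str) -> tuple[float, float]:
        if orientation == "vertical":
            return self.top_d1, self.top_d2
        return self.side_e1, self.side_e2


@dataclass
class StressStrainCurve:
    strain: np.ndarray  # dimensionless, starts at 0, monotone
    stress: np.ndarray  # MPa
    initial_modulus: float | None = None  # MPa
    modulus_window: tuple[int, int] | None = None
    modulus_r2: float | None = None


@dataclass
class MechSummary:
    specimen_id: str
    orientation: str
    stiffness_N_per_mm: float
    stiffness_r2: float
    stiffness_window: tuple[int, int]
    yield_strength_MPa: float | None
    initial_modulus_MPa: float


@dataclass(frozen=True)
class StiffnessOptions:
    min_window: int = 5
    window_fraction: float = 0.20  # minimum window size, as fraction of eligible
    load_range_fraction: float = 0.50  # confine windows to this load range
    contact_threshold: float = 0.02  # fraction of peak load
    smooth_window: int = 0  # optional moving-average strain filter (0 = off)


def deformation_series(
    rec: LoadDeformationRecord, opts: StiffnessOptions = StiffnessOptions()
) -> np.ndarray:
    """Deformation (mm): position re-referenced to the contact point.

    Contact = first sample whose load exceeds ``contact_threshold`` of the
    peak; the reported series is nonnegative by construction and invariant
    to any constant position offset.
    """
    thr = opts.contact_threshold * float(rec.load_N.max())
    above = np.flatnonzero(rec.load_N > thr)
    if len(above) == 0:
        raise NoContactError("no sample above the contact-load threshold")
    i0 = int(above[0])
    ref = rec.position_mm[i0]
    # toe correction: back-extrapolate the early position-load slope to
    # zero load so the threshold choice does not bias the deformation
    # origin; the extrapolation window spans a fixed load increment (10%
    # of the range) so position noise cannot swamp the slope estimate
    target = rec.load_N[i0] + 0.10 * float(np.ptp(rec.load_N))
    j1 = int(np.searchsorted(np.maximum.accumulate(rec.load_N), target, side="right"))
    j1 = min(len(rec.load_N), max(j1, i0 + max(opts.min_window, 5)))
    dF = rec.load_N[i0:j1] - rec.load_N[i0]
    dx = rec.position_mm[i0:j1] - rec.position_mm[i0]
    denom = float(dF @ dF)
    if denom > 0:
        compliance = float(dx @ dF) / denom  # mm per N, noise on position only
        if compliance > 0:
            ref = ref - compliance * rec.load_N[i0]
    d = rec.position_mm - ref
    return np.maximum(d, 0.0)


def _window_fit(x: np.ndarray, y: np.ndarray, w: int):
    """Slope, intercept and R² of all length-w sliding windows (vectorized)."""
    n = len(x)
    c = np.arange(n - w + 1)
    cs = lambda a: np.concatenate([[0.0], np.cumsum(a)])
    Sx, Sy = cs(x), cs(y)
    Sxx, Syy, Sxy = cs(x * x), cs(y * y), cs(x * y)
    sx = Sx[c + w] - Sx[c]
    sy = Sy[c + w] - Sy[c]
    sxx = Sxx[c + w] - Sxx[c]
    syy = Syy[c + w] - Syy[c]
    sxy = Sxy[c + w] - Sxy[c]
    vx = sxx - sx * sx / w
    vy = syy - sy * sy / w
    cxy = sxy - sx * sy / w
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = cxy / vx
        r2 = np.where(vy > 0, cxy * cxy / np.where(vx * vy > 0, vx * vy, np.inf), 0.0)
    intercept = (sy - slope * sx) / w
    return slope, intercept, r2


def stiffness(
    deformation: np.ndarray,
    load: np.ndarray,
    opts: StiffnessOptions = StiffnessOptions(),
) -> tuple[float, tuple[int, int], float]:
    """Slope (N/mm) of the initial linear portion of load vs deformation.

    Returns ``(slope, (start, stop), r2)``.  Candidate windows cover from
    ``window_fraction`` up to all of the eligible samples (those within
    the first ``load_range_fraction`` of the load range); the window with
    the highest R² wins, with near-ties resolved toward larger and then
    earlier windows, so exactly-linear data select the full leading
    segment.  The deformation is regressed on the load (the controlled,
    noise-free axis) and the slope inverted, so position noise does not
    attenuate the stiffness.
    """
    deformation = np.asarray(deformation, float)
    load = np.asarray(load, float)
    if np.ptp(load) == 0:
        raise MechTestError("degenerate fit: load is constant")
    lmax = load.min() + opts.load_range_fraction * np.ptp(load)
    n_elig = int(np.searchsorted(np.maximum.accumulate(load), lmax, side="right"))
    n_elig = max(n_elig, opts.min_window)
    n_elig = min(n_elig, len(load))
    x = deformation[:n_elig]
    y = load[:n_elig]
    if np.ptp(x) == 0:
        raise MechTestError("degenerate fit: deformation is constant")
    w_min = max(opts.min_window, int(math.ceil(opts.window_fraction * n_elig)))
    w_min = min(w_min, n_elig)
    step = max(1, (n_elig - w_min) // 40)
    best = None  # (r2_rounded, w, -start, slope_inv, r2)
    for w in range(w_min, n_elig + 1, step):
        inv_slope, _, r2 = _window_fit(y, x, w)
        i = int(np.argmax(np.round(r2, 12)))
        key = (round(float(r2[i]), 12), w, -i)
        if best is None or key > best[0]:
            best = (key, (i, i + w), float(inv_slope[i]), float(r2[i]))
    _, win, inv, r2b = best
    if inv == 0 or not np.isfinite(inv):
        raise MechTestError("degenerate fit: deformation does not vary with load")
    return float(1.0 / inv), win, r2b


def oval_area(d1: float, d2: float) -> float:
    """Ellipse area π·(d₁/2)·(d₂/2) from two perpendicular diameters."""
    if d1 <= 0 or d2 <= 0:
        raise MechTestError("diameters must be > 0")
    return math.pi * (d1 / 2.0) * (d2 / 2.0)


def to_stress_strain(
    rec: LoadDeformationRecord,
    dims: EpiphysisDims,
    orientation: str | None = None,
    opts: StiffnessOptions = StiffnessOptions(),
) -> StressStrainCurve:
    """Stress = load / oval surface area; strain = deformation / height.

    The loaded surface is the top one for vertical loading and the side
    one for angled loading, each an oval from two caliper diameters.
    """
    orientation = orientation or rec.orientation
    d1, d2 = dims.diameters(orientation)
    area = oval_area(d1, d2)
    d = deformation_series(rec, opts)
    strain = d / dims.height
    stress = rec.load_N / area
    if opts.smooth_window and opts.smooth_window > 1:
        sm = opts.smooth_window
        pad = np.concatenate(
            [np.full(sm // 2, strain[0]), strain, np.full(sm - sm // 2 - 1, strain[-1])]
        )
        strain = np.convolve(pad, np.ones(sm) / sm, mode="valid")
    # restrict to the loading phase from contact on (pre-contact samples
    # carry pure position noise at zero load); the toe-corrected origin is
    # prepended so strain starts at 0.  The monotone strain axis is
    # enforced by isotonic projection, which unlike discarding back-steps
    # does not bias noisy strain toward its upper envelope.
    thr = opts.contact_threshold * float(rec.load_N.max())
    i0 = int(np.flatnonzero(rec.load_N > thr)[0])
    strain = np.concatenate([[0.0], strain[i0:]])
    stress = np.concatenate([[0.0], stress[i0:]])
    strain = _pava(strain)
    curve = StressStrainCurve(strain=strain, stress=stress)
    E0, win, r2 = stiffness(strain, stress, opts)
    curve.initial_modulus = E0
    curve.modulus_window = win
    curve.modulus_r2 = r2
    return curve


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares nondecreasing fit (O(n))."""
    y = np.asarray(y, dtype=float)
    means = []
    counts = []
    for v in y:
        means.append(v)
        counts.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, c2 = means.pop(), counts.pop()
            m1, c1 = means.pop(), counts.pop()
            means.append((m1 * c1 + m2 * c2) / (c1 + c2))
            counts.append(c1 + c2)
    return np.repeat(means, counts)


def _refine_modulus(
    strain: np.ndarray, stress: np.ndarray, E0: float, offset: float
) -> float:
    """Refit the elastic modulus on the full pre-knee range.

    The departure function D(σ) = ε − σ/E₀ is flat (zero) over the elastic
    branch and rises past the knee; its isotonic projection pools the whole
    elastic branch, so the knee is located robustly and the modulus can be
    re-estimated from every elastic sample.  This matters because the
    offset construction tolerates only sub-percent modulus error before
    the offset line grazes the elastic branch itself.
    """
    for _ in range(3):
        D = _pava(strain - stress / E0)
        knee = int(np.searchsorted(D, offset / 2.0))
        knee = max(knee, 8)
        s, t = stress[:knee], strain[:knee]
        vt = float(np.var(s))
        if vt <= 0:
            break
        inv = float(np.cov(s, t, bias=True)[0, 1]) / vt
        if inv <= 0 or not np.isfinite(inv):
            break
        E0 = 1.0 / inv
    return E0


def offset_yield(
    curve: StressStrainCurve,
    offset: float = 0.002,
    refine_modulus: bool = True,
) -> float:
    """Stress (MPa) at the first intersection of the measured curve with
    the initial-modulus line shifted by the strain offset.

    At the intersection of σ = E₀·(ε − offset) with the curve, the
    departure ε − σ/E₀ equals the offset; the crossing is therefore
    located on the isotonic projection of that departure (monotone for a
    softening curve, and exactly the raw departure for clean data) and
    interpolated linearly between the bracketing samples.  A record whose
    departure never reaches the offset did not yield.
    """
    if curve.initial_modulus is None:
        E0, win, r2 = stiffness(curve.strain, curve.stress)
        curve.initial_modulus = E0
    E0 = curve.initial_modulus
    if E0 <= 0:
        raise MechTestError("initial modulus must be positive for yield analysis")
    if refine_modulus:
        E0 = _refine_modulus(curve.strain, curve.stress, E0, offset)
        curve.initial_modulus = E0
    D = _pava(curve.strain - curve.stress / E0)
    if D[-1] < offset:
        raise NoYieldError("offset line does not intersect the curve: no yield")
    i = int(np.searchsorted(D, offset))
    if i == 0:
        return float(curve.stress[0])
    t = (offset - D[i - 1]) / (D[i] - D[i - 1]) if D[i] > D[i - 1] else 1.0
    return float(curve.stress[i - 1] + t * (curve.stress[i] - curve.stress[i - 1]))


def load_for_pressure(target_pressure_MPa: float, dims: EpiphysisDims) -> float:
    """Load (N) producing the target pressure on the oval top surface.

    This is the pressure-matched loading calculation: F = p · π(d₁/2)(d₂/2).
    """
    if target_pressure_MPa < 0:
        raise MechTestError("target pressure must be >= 0")
    return target_pressure_MPa * oval_area(dims.top_d1, dims.top_d2)


def analyze_record(
    rec: LoadDeformationRecord,
    dims: EpiphysisDims,
    opts: StiffnessOptions = StiffnessOptions(),
) -> MechSummary:
    """Full per-specimen analysis: stiffness, modulus and offset yield."""
    d = deformation_series(rec, opts)
    k, win, r2 = stiffness(d, rec.load_N, opts)
    curve = to_stress_strain(rec, dims, opts=opts)
    try:
        sy = offset_yield(curve)
    except NoYieldError:
        logger.info("specimen %s did not yield", rec.specimen_id or "<unnamed>")
        sy = None
    return MechSummary(
        specimen_id=rec.specimen_id,
        orientation=rec.orientation,
        stiffness_N_per_mm=k,
        stiffness_r2=r2,
        stiffness_window=win,
        yield_strength_MPa=sy,
        initial_modulus_MPa=curve.initial_modulus,
    )
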