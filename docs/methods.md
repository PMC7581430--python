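# Methods

## The epiphysis model

The model idealizes the end of a growing long bone as a 2D plane-strain
domain of unit (1 mm) out-of-plane thickness: a semicircular cartilaginous
head (radius 17 mm, centered 49 mm above the base) on a trapezoidal shaft
(bottom width 25 mm, total height 66 mm).  Plane strain is a deliberate
simplification — it keeps the full stress state 3D (the out-of-plane
stress S33 = λ(E11+E22) is carried through all scalar measures) while
making the geometry and boundary conditions transparent.

Five subdomains partition the domain:

| subdomain | default region | E (MPa) | ν |
|---|---|---|---|
| epiphyseal cartilage | head minus band and insert | 6 | 0.47 |
| growth-plate band | head strip y ∈ [49, 52] mm | 6 | 0.47 |
| stiff insert | SOC semi-ellipse or protrusion fingers | 500 | 0.20 |
| cortical bone | 2.5 mm strips along the slanted shaft sides | 5000 | 0.30 |
| metaphyseal bone | shaft interior | 500 | 0.20 |

Cartilage and stiff-insert constants are the standard values for this
model family; cortical and metaphyseal values are this package's own
reconstruction (cortical bone at 5 GPa, metaphysis as dense cancellous
bone) and are configurable, as is every geometric placement below.

The interior partition is likewise a reconstruction, chosen to be
anatomically sensible and fully parametric: the SOC is the upper half of
an ellipse (semi-axes 12 × 8 mm) with its flat base at y = 53 mm, leaving
a 1 mm cartilage seam above the growth-plate band; the band (height 3 mm)
spans the head directly above the metaphysis, where the hypertrophic
chondrocytes sit.  Protrusion variants replace the SOC by five stiff
fingers (2 mm wide, spaced 5 mm, depth 4 mm for the "small" variant and
10 mm for the "extended" one) rising from the head base *through* the
band into the cartilage — the band subdomain is then the strip minus the
fingers, i.e. exactly the "hypertrophic zone free of bony elements" on
which variants are compared.  The `no_soc` variant keeps the SOC polygon
and assigns it cartilage material, so with/without comparisons are
mesh-identical by construction.

### Meshing

Subdomain boundaries are noded into a planar arrangement (shapely), so
adjacent faces carry identical vertex chains along interfaces; each face
is then triangulated by a Delaunay pass over its canonically subdivided
boundary plus a hexagonal interior lattice, and accepted only if the
triangles tile the face area to 1e-9 relative.  Because the subdivision
rule depends only on the segment endpoints and the global target edge
length, interfaces conform exactly across faces.  Only the x ≥ 0 half of
each face is triangulated and then mirrored, which makes the mesh exactly
symmetric about the centerline — a symmetric vertical load then produces
a discretely symmetric solution (to solver precision), not merely a
symmetric-to-discretization-error one.  Arc nodes are snapped onto the
true circle after assembly.  The mesher rejects target edge lengths much
larger than the smallest feature (the 1 mm cartilage seam); in practice
targets ≤ 2.5 mm mesh all variants, and the production default is 0.9 mm
(~5000 triangles).

## Finite-element solver

Kinematics are finite-strain total-Lagrangian: F = I + ∇u,
E = ½(FᵀF − I), with a Saint Venant–Kirchhoff material
S = λ tr(E) I + 2μ E — "linearly elastic constants with nonlinear
strains".  Elements are 6-node quadratic triangles with 3-point
quadrature; quadratic interpolation avoids the volumetric locking that
linear triangles exhibit at ν = 0.47.  A small-strain path (identical
assembly with F ≡ I and the symmetric gradient) exists for verification
against closed forms and for low-load linearization checks.

Boundary conditions: bottom edge u_y = 0, outer cortical edges u_x = 0,
everything else traction-free except the loaded sector.  The load is a
pressure on a 45° sector of the top arc, maximal at the sector center and
falling quadratically to zero at the sector borders:
p(θ) = p̂·max(0, 1 − ((θ−θc)/Δ)²), Δ = 22.5°.  The phrase "to zero on the
two neighboring sector borders" admits a second reading in which the
support spans the two neighboring sectors (Δ_eff = 67.5°); both are
implemented (`wide_support`), the narrow reading is the default, and the
cross-variant comparisons are exercised under both.  The pressure is a
follower load by default (direction and magnitude track the deforming
surface; its exact load-stiffness contribution is included in the
tangent), with a dead-load option.

Each load step is solved by full Newton with a backtracking line search
on the residual norm; tolerance 1e-8 relative to the step's initial
residual, 25 iterations per step, automatic step halving (up to 4) on
divergence.  Loads ramp in 1 step at physiological pressure (0.3 MPa) and
10 at supra-physiological; prescribed displacements ramp with the same
factor.  Element inversion is tolerated at intermediate iterates (the
material law needs no det F > 0) but a converged state containing an
inverted element is rejected.  Linear systems use sparse LU; the tangent
is unsymmetric when follower loading is active.

Verification: the homogeneous-block fixture reproduces the plane-strain
closed form u_top = −p·h·(1−ν²)/E to better than 0.5 % and the uniform
stress state (σ_yy = −p, σ_xx = 0, σ_zz = −νp) to 1 %; an imposed affine
displacement field is reproduced to 1e-10 (patch test); halving the mesh
target changes the apex deflection of the default model by < 1 %.

### Load-carrying limit at supra-physiological pressure

A Saint Venant–Kirchhoff solid softens in nominal stress under
compression: in plane-strain uniaxial response the nominal traction peaks
at λ₂ = 1/√3 with magnitude 0.1925·E/(1−ν²) — for the cartilage constants
(6 MPa, 0.47) about **1.47 MPa**.  Where the loaded surface is soft and
only weakly confined (the cartilage head under a 45° sector whose
high-pressure zone is narrow compared to the soft-layer depth), the local
response is close to this uniaxial mode, so a *pressure-controlled* load
above ~1.47 MPa has no equilibrium to find.  High-effort continuation (60
load steps, 8 halvings, line-searched full Newton) stalls at 1.42–1.46
MPa peak pressure for both the SOC-free and SOC-bearing variants,
independent of quadrature degree, mesh density, load-support reading and
follower/dead loading — a constitutive limit, not a solver artifact.
The supra-physiological 3 MPa case therefore cannot be equilibrated by
this model as specified; the solver reports the certified limit fraction,
the corresponding acceptance checks fail loudly rather than report
stresses from a non-equilibrium state, and all cross-variant directional
conclusions are instead established at 1.2 MPa (four times physiological,
~80 % of the limit) and at the physiological 0.3 MPa, where they hold
under both load-support readings:

* peak band octahedral shear: with SOC < without; protrusions < without;
* apex deflection: with SOC < protrusions < without;
* under the angled (45°, from the right) load the band's peak compressive
  principal stress falls in the left third — the side opposite the load,
  matching the observed localization of chondrocyte death;
* under vertical load the band's compressive hydrostatic stress is
  elevated in its middle third.

One published property is *not* reproduced by this reconstruction: with
metaphysis-rooted, bone-stiff fingers the protrusion variant deflects
noticeably less than the SOC-free model (the fingers act as axial
columns), rather than matching it within 20 %.  The qualitative claim —
protrusions shield the band without achieving the SOC's stiffening — holds.

## Stress post-processing

Stresses are reported per element as quadrature averages at reference
centroids, deliberately without nodal smoothing: zone peaks must not be
diluted across material interfaces.  Principal stresses come from the
2×2 in-plane closed form plus S33; the three scalar measures are
hydrostatic stress (full 3D trace), lowest principal stress (reported
unclamped and logged if tensile), and octahedral shear τ_oct = √(2J₂/3).
Figure conventions flip the sign of the first two ("compressive
positive"); computation never does.  Zone summaries give the peak and
area-weighted mean over the growth-plate band and its left/middle/right
thirds (equal-width in centroid x).  Deflection is the displacement
magnitude of the arc node nearest the load-sector center, and deformed
shapes are x = X + u at scale exactly 1.

## Mechanical-test analysis

Records are (position, load) samples at a 0.1 N/s load ramp.  Where the
experimental description is silent the package fixes conventions and
documents them:

* **Contact and deformation.**  Contact is the first sample above 2 % of
  peak load; the deformation origin is back-extrapolated to zero load
  using the position–load slope over the first 10 % of the load range, so
  the threshold choice does not bias the origin.  No machine-compliance
  correction is applied (none is described).
* **Stiffness.**  Slope of the initial linear portion: sliding windows
  from 20 % up to 100 % of the samples within the first half of the load
  range, best R² wins, near-ties resolving to larger and then earlier
  windows (so exactly-linear data select the full leading segment).  The
  regression is position-on-load — the load axis is machine-controlled
  and noise-free — and the slope inverted, avoiding the attenuation bias
  that position noise induces in the direct regression.
* **Stress and strain.**  Load over the oval loaded surface
  (π·(d₁/2)(d₂/2) from two caliper diameters; top surface for vertical,
  side surface for angled loading); deformation over the epiphysis
  height.  The strain axis is made monotone by isotonic projection
  (pool-adjacent-violators), which unlike discarding back-steps does not
  bias toward the upper noise envelope.
* **0.2 % offset yield.**  At the intersection of σ = E₀(ε − offset) with
  the curve, the departure D(σ) = ε − σ/E₀ equals the offset; the
  crossing is located on the isotonic projection of D (exactly the raw
  departure for clean data) and interpolated between bracketing samples.
  Because the construction tolerates well under 1 % modulus error before
  the offset line grazes the elastic branch itself, E₀ is refined by
  locating the knee of D and refitting on the full pre-knee range.
* **Pressure-matched loading.**  F = p·π·(d₁/2)(d₂/2) inverts the stress
  definition; 0.023 MPa on an 8.70 mm² oval gives the 0.2 N reference.

On 200 synthetic records with 1 % (of travel) position noise, median
recovery error is ~1 % for stiffness and ~2 % for yield.  The error
distribution is heavy-tailed: per-sample strain noise several times the
0.002 offset means individual records can still fail catastrophically;
medians, not tails, are the meaningful summary at this noise level.

## Hertz indentation fitting

Units are µm / nN / kPa (1 kPa = 1 nN/µm² exactly, so
F = (4/3)·E/(1−ν²)·√R·δ^{3/2} needs no conversion constants).  AFM
kinematics subtract the cantilever deflection from piezo travel
(δ = (z − z₀) − F/k); the nanoindenter reports probe indentation
directly.  The modulus and contact point (optionally a force baseline)
are fitted jointly by bounded least squares on the force residuals, with
E parameterized in log space; fitting is restricted to non-negative
forces (excluding the retract adhesion well) and to δ ≤ 10 % of the tip
radius (AFM) or 5 µm (nanoindenter).  The Poisson ratio is assumed, not
fitted (default 0.5, incompressible), so E is an effective modulus.
Fits are flagged invalid — never raised — when the optimizer stops at a
modulus bound, when no indentation exists at the fitted contact point
(rigid surface), or when the residual RMS exceeds 20 % of peak force.
No bottom-effect (finite thickness) correction is applied.  Aggregation
offers mean ± SD over valid fits and per-unit medians (robust to the
right-skewed modulus distributions of tissue) with a cross-unit mean.

## Allometry

D = k·BMᵃ with presets a = 0.366 (ungulates), 0.3944
(insectivores/rodents), 0.364 with k = 1.26 (combined quadrupeds), 0.5
(full pressure compensation).  Pressure on the growth plate scales as
BM/D² = BM^(1−2a); the thousandfold-mass folds are 6.3, 4.3 and 6.5 under
the three exponents, and a = 0.5 gives exactly 1.  The units of k are not
printed in the source regression, so only ratio-based quantities are
exposed as unit-safe.  Reported folds round to one decimal, half-even, at
the reporting layer only.

## Synthetic fixtures

Generators are deterministic in (parameters, seed) and embed their ground
truth in the returned metadata.  Force curves superpose additive i.i.d.
Gaussian force noise (default 2 % of peak) on exact Hertzian contact with
the study hardware presets (AFM: 5 µm sphere, k ∈ [0.06, 0.09] N/m,
10 % · R depth; nanoindenter: R = 45.5 µm, k = 4.14 N/m, 5 µm depth); the
AFM forward model solves the implicit cantilever–sample force balance, so
noiseless curves round-trip the fitter to machine precision.  Mechanical
records are bilinear (post-knee tangent 20 % of elastic — a documented
convention for recovery testing only), sampled at 10 Hz under the 0.1 N/s
ramp to 1.5× the knee load, with Gaussian position noise (default 1 % of
travel) and a pre-contact approach segment; metadata includes the
closed-form offset-yield implied by the bilinear curve.  The block
fixture provides the plane-strain closed form; the tensor generator
stores eigenvalues from a generic eigensolver and invariants (trace,
√(2J₂/3)) computed independently of the closed-form routines they check.
Not emulated: piezo hysteresis, thermal drift, cantilever tilt,
viscoelastic relaxation — passing recovery tests show estimator
correctness under the stated noise model, not robustness to instrument
artifacts.

## Problem sizes

Default test sizes are chosen for fast, deterministic runs: coarse
epiphysis meshes at 2 mm (~1200 triangles) for solver property tests, the
production 0.9 mm mesh (~5000 triangles, with a 0.45 mm halving check)
for the figure-level acceptance runs, 100 force curves and 200
load–deformation records for recovery studies, and 10⁴ random tensors for
the stress-measure identities.
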