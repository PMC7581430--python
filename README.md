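# epimech

Biomechanics of the cartilaginous epiphysis: why does a secondary
ossification center (SOC) form inside the growing end of a long bone?

Growth plates are driven by hypertrophic chondrocytes — enormous, very
soft cells that turn out to be mechanically the most vulnerable population
in the tissue.  In terrestrial animals the epiphysis develops a bony SOC
that splits the original cartilage into articular cartilage and growth
plate.  `epimech` implements, as a reusable and tested Python package, the
computational side of the case that the SOC is a protective adaptation:

* a **parametric 2D plane-strain finite-element model** of an idealized
  epiphysis (semicircular cartilage head atop a trapezoidal bone shaft,
  five tissue subdomains) in which candidate regions — a semi-elliptical
  SOC, or finger-like ossified protrusions as found in archosaurs — can be
  switched between cartilage and bone stiffness on an identical mesh;
* a **total-Lagrangian Saint Venant–Kirchhoff solver** (6-node triangles,
  incremental Newton with line search, follower sector pressure) with
  2nd Piola–Kirchhoff stress recovery and the three scalar measures used
  to characterize chondrocyte loading: hydrostatic stress, lowest
  principal stress, and octahedral shear stress
  τ_oct = ⅓√((s₁−s₂)²+(s₂−s₃)²+(s₃−s₁)²);
* **ex-vivo mechanical-test analysis**: contact-referenced deformation,
  stiffness from the initial linear portion, stress over the oval loaded
  surface, strain over the epiphysis height, 0.2 %-offset yield strength,
  and pressure-matched load computation (F = p·π·(d₁/2)(d₂/2));
* **Hertz contact fitting** of AFM / nanoindenter force–distance curves,
  F = (4/3)·E/(1−ν²)·√R·δ^{3/2}, with joint (E, z₀) estimation and
  per-cell / per-animal aggregation;
* **allometric scaling**: stylopod diameter D = k·BMᵃ and the implied
  growth-plate pressure fold BM^(1−2a);
* **synthetic fixtures** with known ground truth for every analysis path,
  so the whole package is testable without any instrument data.

Tissue constants default to the literature values for this model family:
cartilage E = 6 MPa, ν = 0.47; stiff (SOC / dense cancellous) bone
E = 500 MPa, ν = 0.20 — an ~83-fold stiffness contrast.

## Worked example

```python
from epimech import (EpiphysisParams, VariantId, build_geometry, generate_mesh,
                     BoundaryConditions, LoadCase, default_materials,
                     assemble_and_solve, second_pk_stress, scalar_measures,
                     zone_summary, deflection, SubdomainLabel)

params = EpiphysisParams()                   # 66 mm high, 17 mm head radius
bc = BoundaryConditions.epiphysis_default()  # bottom: u_y = 0; cortical sides: u_x = 0
load = LoadCase(peak_pressure=0.3, sector_center_angle=90.0)  # physiological, vertical

for variant in (VariantId.NO_SOC, VariantId.WITH_SOC, VariantId.PROTRUSIONS_EXTENDED):
    mesh = generate_mesh(build_geometry(params, variant), 0.9)
    mat = default_materials(stiff_insert=variant is not VariantId.NO_SOC)
    sol = assemble_and_solve(mesh, mat, bc, load)
    sc = scalar_measures(second_pk_stress(sol, mesh, mat))
    band = mesh.elements_with_label(SubdomainLabel.GROWTH_PLATE_BAND)
    peak = zone_summary(sc, mesh, band).peak["tau_oct"]
    print(variant.value, round(deflection(sol, mesh, load), 3), round(peak, 4))
```

prints

```
no_soc 0.372 0.0644
with_soc 0.145 0.0201
protrusions_extended 0.213 0.0171
```

i.e. under a vertical physiological load (0.3 MPa peak) the SOC cuts the
apex deflection from 0.372 mm to 0.145 mm (a stiffer joint) and reduces
the peak octahedral shear stress in the hypertrophic growth-plate band
from 0.064 MPa to 0.020 MPa; ossified protrusions shield the band just as
well (0.017 MPa) while stiffening the joint less (0.213 mm) — the two
skeletal adaptations protect the same cells by different routes.

A CLI covers the same ground (`epimech simulate --config run.yaml`,
`epimech mech-test`, `epimech fit-hertz`, `epimech allometry`,
`epimech make-fixtures`).

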