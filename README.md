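# cryovessel

Hyperelastic characterisation of PVA/gelatin cryogels and semi-analytic
simulation of multi-layered coronary-artery grafts.

Synthetic vascular grafts fail, in large part, because their wall mechanics
do not match the artery they replace: a mismatch in compliance and in the
transmural (through-wall) distribution of stress and strain disturbs the
mechanical environment of the endothelium. Multi-layered grafts that mimic
the intima / media / adventitia structure of the arterial wall are one route
around this. `cryovessel` is a toolkit for designing and evaluating such
grafts *in silico*, using poly(vinyl alcohol)/gelatin cryogel — a soft,
biocompatible, strain-stiffening hydrogel — as the wall material. It is
aimed at biomaterials and cardiovascular-biomechanics researchers who want
to go from uniaxial compression tests of candidate materials to predicted
vessel-level mechanics without a finite-element license.

## What it computes

**Constitutive models.** Isotropic incompressible strain-energy functions
of the polynomial family,

  U = Σ_{i+j=1..N} C_ij (Ī₁−3)^i (Ī₂−3)^j,

its reduced (first-invariant) form with the neo-Hookean (N=1), Mooney–Rivlin
and Yeoh (N=3) special cases, and the Ogden form in principal stretches,

  U = Σ_i (2μ_i/α_i²) (λ₁^{α_i} + λ₂^{α_i} + λ₃^{α_i} − 3).

Closed-form nominal stresses are provided for uniaxial, equibiaxial and
planar deformation, together with the initial shear modulus μ₀ — the common
currency for comparing parameter sets across families — and a Drucker
stability screen (stress must rise strictly with stretch in every mode over
λ ∈ [0.5, 2]).

**Calibration.** Force–displacement records are converted to engineering
stress–strain (σ = F/A, ε = ΔL/L₀), decimated with a two-interval sampling
rule (every 40th point below 25 % strain, every 20th above), and fitted by
least squares: exactly for the coefficient-linear families, by bounded
multi-start nonlinear least squares for Ogden. Fit quality is the squared
Pearson correlation r²; per-composition parameters are aggregated as
mean ± SD with the mirrored α₁ < 0 Ogden branch excluded.

**Vessel inflation.** A three-layer thick-walled incompressible cylinder,
axially constrained (λ_z = 1) and embedded in soft connective tissue
(Hookean annulus, E = 0.05 MPa, ν = 0.49), is inflated quasi-statically.
The deformed luminal radius solves the pressure balance
P = ∫ (σ_θ − σ_r) dr/r; radial and hoop Cauchy-stress profiles, layer
means, pressure–strain curves and compliance
(A_sys − A_dia)/A_dia between 80 and 120 mmHg follow.

**Graft comparison.** Graft and artery profiles are resampled onto a common
transmural coordinate and differenced point-by-point
((graft − artery)/artery × 100 %), design targets are checked (hoop stress
concentrated in the intima; radial stress magnitude decaying outward;
strain stiffening between 0 and 120 mmHg), and a batch report ranks the
four graft layups (PG-1..PG-4) against three literature artery models
(polynomial, reduced polynomial, Ogden).

Because no raw compression data are publicly deposited, a seeded synthetic
generator reproduces the experiments' statistical structure (coefficients
drawn from the published per-composition mean ± SD, load-cell-like noise)
so every stage is testable offline.

## Worked example

```python
from cryovessel import (artery_model, graft_layup, inflate, compliance,
                        relative_difference, initial_shear_modulus,
                        drucker_stability)
from cryovessel import fixtures as fx

mat = fx.cryogel_material("P9G1-A-C", "ogden")   # stiffest cryogel
print(initial_shear_modulus(mat))                 # 0.158 MPa
print(drucker_stability(mat).stable)              # True

artery = artery_model("ogden")                    # 3-layer coronary model
res = inflate(artery, 120.0)                      # systolic pressure, mmHg
print(res.luminal_radius_deformed_mm)             # 1.765 mm (from 1.5 mm)
print(res.profile.sigma_theta[0])                 # 0.0621 MPa at the lumen
print(res.profile.sigma_r[0])                     # -0.0160 MPa = -P

graft = graft_layup("PG-1", "ogden")
print(100 * compliance(artery))                   # 8.16 %
print(100 * compliance(graft))                    # 11.82 %
diff = relative_difference(inflate(graft, 120.0).profile, res.profile)
print(diff.luminal["sigma_theta"])                # -60.2 %
```

Reading: at systole the artery model carries its peak hoop stress
(0.062 MPa) at the luminal surface while the radial stress there equals the
applied pressure (0.016 MPa); the PG-1 graft is ~45 % more compliant than
the artery and its luminal hoop stress is 60 % lower — the compliant-graft
signature that motivates stiffer strain-stiffening cryogel formulations.

The same workflows are available from the shell via the `cryovessel`
console script (`synth`, `fit`, `stability`, `inflate`, `compare`,
`report`), e.g.

```
cryovessel inflate artery:ogden --pressures 120 --out out/
cryovessel report --out out/
```

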