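# Methods

This note records the models implemented in `cryovessel`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data can and cannot establish.

## Constitutive models

All materials are isotropic, incompressible hyperelastic solids. The
polynomial family and its reductions are functions of the deviatoric
Cauchy–Green invariants Ī₁, Ī₂; the Ogden family is a function of principal
stretches with the `2μᵢ/αᵢ²` prefactor (the convention used by the common
commercial FE fitting routines, from which the shipped cryogel coefficients
originate). Volumetric `Dᵢ` coefficients are carried on material cards for
fidelity to the published artery sets but never used: hydrogels and
arterial tissue are conventionally treated as incompressible, and the whole
evaluation path enforces unit Jacobian.

Nominal (first Piola) stresses are closed forms per loaded axis:

* uniaxial, path (λ, λ^−½, λ^−½): P = 2(λ − λ⁻²)(∂U/∂Ī₁ + λ⁻¹ ∂U/∂Ī₂)
* equibiaxial, path (λ, λ, λ⁻²): P = 2(λ − λ⁻⁵)(∂U/∂Ī₁ + λ² ∂U/∂Ī₂)
* planar, path (λ, 1, λ⁻¹): P = 2(λ − λ⁻³)(∂U/∂Ī₁ + ∂U/∂Ī₂)

and the corresponding stretch-power forms for Ogden. Each equals the
derivative of the strain energy along the mode's path divided by the number
of worked axes (two for equibiaxial); the test suite verifies this against
central finite differences at random materials and stretches to 1e−6
relative error. Compression is handled through λ = 1 − ε, and compressive
stresses and strains are reported as magnitudes.

### Two shear-modulus conventions (deliberate)

`initial_shear_modulus` implements the reporting convention used with the
shipped parameter tables: 2(C₁₀+C₀₁) for the polynomial family, 2C₁₀ for the
reduced family, and ½Σμᵢαᵢ for Ogden. That last formula belongs to the
*classical* Ogden prefactor; for the `2μ/α²` energy actually implemented,
the true small-strain tangent is Σμᵢ, exposed as `tangent_shear_modulus`.
The two coincide only at α = 2. The package keeps both on purpose: the
½Σμα values are the currency in which the shipped tables and the
artery-vs-graft stiffness gaps (0.255 vs 0.074 MPa) are expressed, so they
are what cross-family comparisons must use, while the tangent modulus is
what physical small-strain checks (uniaxial slope = 3μ at λ = 1) must use.
Supporting evidence that the tables follow the ½Σμα convention: the Yeoh
and Ogden fits of the same cryogel data give 2C₁₀ ≈ 0.041 MPa and
Σμᵢ = 0.0444 MPa — tangent moduli of two fits of one dataset agree, as they
must — while the tabulated Ogden μ₀ is 0.157 MPa = ½μ₁α₁.

### Drucker screening

Stability is screened as strict monotonicity of nominal stress in stretch,
per mode and per branch (tension/compression), on a uniform grid over
λ ∈ [0.5, 2.0] with step 0.005. The range covers the 50 % compressive
strain of the test protocol plus an equal tensile margin; the verdicts for
the shipped materials are invariant under halving the step. This is the
one-dimensional operational form of the criterion (positive incremental
work in the probed modes), not full tangent-moduli positive-definiteness;
it is the form that is checkable from uniaxial-calibrated models without
committing to a particular FE package's internal convention. All nine
artery layer sets and all cryogel mean sets pass over the full range;
Mooney–Rivlin sets with dominant negative C₀₁ fail, reproducing the known
fragility of that form on strain-stiffening data.

## Calibration

* Conversion: σ = |F|/A in MPa, ε = |ΔL|/L₀, curves anchored at (0, 0).
* Decimation: every 40th point below 25 % strain, every 20th at or above,
  endpoints always kept; this is pure index decimation (the literal
  sampling rule), with no moving average. The denser sampling above 25 %
  strain is itself the weighting mechanism, so the least squares is
  unweighted.
* Linear families are solved exactly by `numpy.linalg.lstsq` (the uniaxial
  stress is linear in the C_ij); rank deficiency is flagged, not raised.
* Ogden is solved by `scipy.optimize.least_squares` with bounds
  μ₁ ∈ (0, 10] MPa, α₁ ∈ (0, 50] — brackets every plausible cryogel value
  by an order of magnitude — multi-started at α₁ ∈ {2, 4, 6, 8, 10, 12}
  with μ₁ seeded from the small-strain slope. A compression-only fit has a
  mirrored, nearly equivalent α₁ < 0 solution branch; it is reachable only
  through an explicit option, and aggregation excludes α₁ < 0 fits so that
  branches are never averaged together.
* Fit quality is the squared Pearson correlation between observed and model
  stress magnitudes — a correlation measure, deliberately not 1 − SSE/SST.
* Aggregation reports mean ± SD per coefficient (sample SD, ddof = 1) and
  can exclude a caller-supplied sample list so that all families are
  summarized over one common sample set.

## Vessel inflation

Kinematics: incompressible, axially constrained (λ_z = 1), so
r(R) = √(R² − R_i² + r_i²), λ_θ = r/R, λ_r = 1/λ_θ. Every material point
deforms along the planar path (1/λ, λ, 1), giving
σ_θ − σ_r = λ_θ P_planar(λ_θ). The deformed luminal radius is the root of

P_in − P_out(r_i) = ∫_{R_i}^{R_o} P_planar(λ_θ(R)) / r(R) dR,

found by bracket expansion plus Brent's method (|residual| < 1e−10 MPa);
the integral uses adaptive quadrature (relative tolerance 1e−9) piecewise
per layer. σ_r is recovered by cumulative quadrature from the lumen
(σ_r = −P there, exactly) and σ_θ = σ_r + λ_θ P_planar. Layers are bonded:
σ_r is continuous at interfaces, σ_θ may jump. Under a quasi-static,
axisymmetric, axially constrained load this reduced problem is equivalent
to a full 3-D solve up to end effects; interfacial friction has no work
conjugate here and is dropped.

Choices and defaults:

* **Luminal radius 1.5 mm.** The unloaded radius is not a measured input
  anywhere in the source data; 1.5 mm is a coronary-scale assumption
  (radius-to-thickness ratio ≈ 1.7 with the 0.87 mm wall — firmly
  thick-walled) and is echoed in every result object. Absolute stress and
  strain magnitudes scale with it; orderings and qualitative features do
  not, which is why the cross-model checks are run over 1.2–2.0 mm.
* **Layer thicknesses 0.23 / 0.30 / 0.34 mm** (intima / media /
  adventitia), for grafts and arteries alike.
* **External support.** A plane-strain Hookean annulus (E = 0.05 MPa,
  ν = 0.49) with fixed outer face at 5× the vessel outer radius, applied as
  a radial stiffness k = 2a(λ̄ + G + G b²/a²)/(b² − a²) from the Lamé
  solution (k → 2G/a as b → ∞, k → 0 as E → 0). Traction-free and
  constant-external-pressure modes exist for sensitivity studies.
* **Load path.** The material is hyperelastic and the solve quasi-static,
  so the response is path-independent; each target pressure is solved
  directly, with 80/120 mmHg as the diastole/systole defaults for
  compliance. Pressures are accepted in mmHg only (×133.322 Pa/mmHg
  internally) to prevent silent unit errors.
* **Profiles.** 64 samples per layer, uniform in reference radius; layer
  summaries are unweighted spatial mean ± SD. Strains are reported as
  engineering-strain magnitudes.

Verified invariants: annular-area conservation to machine precision, the
finite-difference equilibrium residual dσ_r/dr − (σ_θ−σ_r)/r below
1e−4 MPa/mm inside layers, σ_r interface jumps below 1e−8 MPa, thin-wall
(t/R = 0.01) layer-mean hoop stress within 2 % of the Laplace estimate
P·r/t, and luminal σ_θ stable to < 0.01 % under refinement of sampling and
quadrature tolerance.

## Graft comparison

Profiles are resampled onto a normalized transmural coordinate (0 = lumen,
1 = outer surface, interfaces aligned to the reference profile's thickness
fractions, piecewise linear within layers, 201 points) before the pointwise
relative difference (graft − artery)/artery × 100 % is taken; points where
the reference is numerically zero are masked, since hoop stress changes
sign inside the media. Design targets are evaluated on layer means by
default (interface values optional): I — σ_θ,intima > σ_θ,media ≤
σ_θ,adventitia; II — |σ_r| strictly decreasing outward; III — strain
stiffening, operationalized as the secant slope of intima hoop strain over
80–120 mmHg being smaller than over 0–80 mmHg (no published formula exists;
a concavity test on the two physiological sub-ranges is the minimal
commitment). The "order of magnitude" separation between hoop and radial
stress is checked as peak σ_θ > 3× peak |σ_r|: the separation is
geometry-dependent (≈ 3.4–5.3 at the default radius, ≈ 7 for the published
geometry), and the load-bearing content of the check is the separation plus
the monotone outward decay, not a factor of exactly ten.

## Synthetic data

The generator emulates the stabilized 10th-cycle compression experiments:
per sample, (μ₁, α₁) or (C₁₀, C₂₀, C₃₀) are drawn from truncated normal
populations with the published per-composition means and SDs (truncations
μ₁ > 0, α₁ > 2, C₁₀ > 0 keep draws physical and match the observed
|α₁| > 2), the uniaxial stress magnitude is evaluated on 1000 strain points
over [0, 0.5], and noise is applied — 1 % multiplicative plus 0.0005 MPa
additive Gaussian, then clipping at zero. The noise magnitudes are not
measured quantities (the true load-cell noise is unpublished); they were
chosen once as a plausible resolution floor for a 220 N cell reading
sub-newton forces, such that decimated fits land in the published r²
regime. Between-sample variability enters only through the coefficient
draws: the published tables carry no information about curve-level
autocorrelated noise, drift, or preconditioning residue, and the generator
does not invent any.

Consequences: passing the recovery and fit-quality tests shows the
estimator chain is unbiased and well-conditioned *under this noise model*;
it does not establish robustness to instrument drift, slip at the platen,
or strain-rate effects, none of which are modelled. Cyclic softening and
hysteresis are out of scope (curves represent the stabilized cycle
directly).

## Problem sizes

Default test and acceptance runs use 6 curves per composition for fit
studies (matching the n = 6 included samples per composition after branch
exclusion), 50 samples for population-recovery checks, 1000-point raw
curves decimated to 39 points, and 8–96 profile samples per layer depending
on whether a scalar (radius, compliance) or a field (equilibrium residual)
is being examined. These sizes were chosen so each check is comfortably
resolved; all are parameters, not constants.

## Known limitations

* Isotropic, time-independent models only: no viscoelasticity, no fibre
  anisotropy, no Mullins effect. The quasi-static loading makes this
  defensible; dynamic or cyclic questions need different constitutive
  machinery.
* No residual stress (opening angle) and λ_z = 1: luminal hoop-stress peaks
  are therefore upper-ish estimates; published comparisons including
  residual stress show the same qualitative trends with reduced peaks.
* The absolute magnitudes of stress, strain and compliance depend on the
  assumed luminal radius and the soft-tissue block geometry; only
  orderings, locations of extrema, continuity/jump structure and
  concavity statements are treated as reproducible claims.
* The semi-analytic solver has no bending, end effects, or contact
  sliding; it cannot represent non-axisymmetric geometries (bifurcations,
  curvature, eccentric lumens).
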