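"""Isotropic hyperelastic strain-energy families and their closed-form responses.

The families implemented here are the phenomenological models routinely used
for rubbery, near-incompressible solids (hydrogels, arterial tissue):

* polynomial in the deviatoric Cauchy–Green invariants,
  ``U = sum_{i+j>=1, i+j<=N} C_ij (I1-3)^i (I2-3)^j``
* reduced polynomial (second invariant dropped), ``U = sum C_i0 (I1-3)^i``
* named special cases: neo-Hookean (1st-order reduced polynomial),
  Mooney-Rivlin (1st-order polynomial), Yeoh (3rd-order reduced polynomial)
* Ogden in principal stretches,
  ``U = sum_i (2 mu_i / alpha_i^2) (l1^a_i + l2^a_i + l3^a_i - 3)``
* a Hookean linear-elastic material (used only for the soft-tissue support
  around an embedded vessel, never for stress evaluation here).

All evaluation is incompressible (unit Jacobian): volumetric ``D_i``
coefficients are stored for fidelity to published parameter sets but never
enter the energy or stress.  Nominal (first Piola) stresses are returned per
loaded axis for the three homogeneous test modes:

==============  ==========================  =========================
mode            principal stretches         work-conjugacy
==============  ==========================  =========================
uniaxial        (l, 1/sqrt(l), 1/sqrt(l))   P = dW/dl
equibiaxial     (l, l, 1/l^2)               P = (1/2) dW/dl (two axes)
planar          (l, 1, 1/l)                 P = dW/dl
==============  ==========================  =========================

where ``W(l)`` is the strain energy along the mode's incompressible path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FAMILIES",
    "MODES",
    "HyperelasticMaterial",
    "StabilityReport",
    "strain_energy",
    "nominal_stress",
    "initial_shear_modulus",
    "tangent_shear_modulus",
    "drucker_stability",
    "neo_hookean",
    "mooney_rivlin",
    "yeoh",
    "ogden",
    "reduced_polynomial",
    "polynomial",
    "linear_elastic",
]

FAMILIES = (
    "neo_hookean",
    "mooney_rivlin",
    "polynomial",
    "reduced_polynomial",
    "yeoh",
    "ogden",
    "linear_elastic",
)

MODES = ("uniaxial", "equibiaxial", "planar")

#: number of worked axes per mode (work-conjugacy factor between dW/dl and
#: the per-axis nominal stress)
_MODE_AXES = {"uniaxial": 1, "equibiaxial": 2, "planar": 1}

_INCOMP_TOL = 1e-9


class ConfigurationError(ValueError):
    """Family/coefficient mismatch or invalid model configuration."""


def _poly_terms(order: int) -> list[tuple[int, int]]:
    """(i, j) exponent pairs of an order-N polynomial energy, 1 <= i+j <= N."""
    return [(i, j) for s in range(1, order + 1) for i in range(s, -1, -1) for j in [s - i]]


@dataclass(frozen=True)
class HyperelasticMaterial:
    """One hyperelastic parameter set with units fixed to MPa.

    Parameters
    ----------
    family:
        One of :data:`FAMILIES`.
    order:
        Polynomial/Ogden order ``N >= 1``.  Implied (and checked) for the
        named special cases.
    c:
        Invariant coefficients ``C_ij`` keyed by ``(i, j)`` in MPa, for the
        polynomial-type families.
    mu, alpha:
        Ogden shear coefficients (MPa) and dimensionless exponents.
    d:
        Volumetric ``D_i`` coefficients (1/MPa).  Stored only; the
        incompressible evaluation path ignores them.
    E, nu:
        Young's modulus (MPa) and Poisson ratio, ``linear_elastic`` only.
    """

    family: str
    order: int = 1
    c: Mapping[tuple[int, int], float] = field(default_factory=dict)
    mu: tuple[float, ...] = ()
    alpha: tuple[float, ...] = ()
    d: tuple[float, ...] = ()
    E: float | None = None
    nu: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.order < 1:
            raise ConfigurationError("order must be >= 1")
        object.__setattr__(self, "c", dict(self.c))
        object.__setattr__(self, "mu", tuple(self.mu))
        object.__setattr__(self, "alpha", tuple(self.alpha))
        object.__setattr__(self, "d", tuple(self.d))
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        fam = self.family
        if fam == "linear_elastic":
            if self.E is None or self.nu is None:
                raise ConfigurationError("linear_elastic needs E and nu")
            if not (self.E > 0 and 0 < self.nu < 0.5):
                raise ConfigurationError("need E > 0 and 0 < nu < 0.5")
            return
        if fam == "ogden":
            if len(self.mu) != self.order or len(self.alpha) != self.order:
                raise ConfigurationError(
                    f"Ogden order {self.order} needs {self.order} (mu, alpha) pairs"
                )
            if any(a == 0 for a in self.alpha):
                raise ConfigurationError("Ogden exponents must be nonzero")
            return
        expected = self._expected_terms()
        extra = set(self.c) - set(expected)
        if extra:
            raise ConfigurationError(f"unexpected coefficients {sorted(extra)} for {fam}")
        missing = set(expected) - set(self.c)
        if missing:
            raise ConfigurationError(f"missing coefficients {sorted(missing)} for {fam}")

    def _expected_terms(self) -> list[tuple[int, int]]:
        fam = self.family
        if fam == "neo_hookean":
            if self.order != 1:
                raise ConfigurationError("neo-Hookean is first order")
            return [(1, 0)]
        if fam == "mooney_rivlin":
            if self.order != 1:
                raise ConfigurationError("Mooney-Rivlin is first order")
            return [(1, 0), (0, 1)]
        if fam == "yeoh":
            if self.order != 3:
                raise ConfigurationError("Yeoh is third order")
            return [(1, 0), (2, 0), (3, 0)]
        if fam == "reduced_polynomial":
            return [(i, 0) for i in range(1, self.order + 1)]
        return _poly_terms(self.order)

    # -- properties -------------------------------------------------------

    @property
    def uses_invariants(self) -> bool:
        return self.family not in ("ogden", "linear_elastic")

    @property
    def n_coefficients(self) -> int:
        if self.family == "ogden":
            return 2 * self.order
        if self.family == "linear_elastic":
            return 2
        return len(self.c)

    # -- serialization (material cards) -----------------------------------

    def to_card(self) -> dict:
        """Named-key JSON card: c10, c01, ..., mu1, alpha1, ..., d1, E, nu."""
        card: dict = {"label": self.label, "family": self.family, "order": self.order}
        for (i, j), v in sorted(self.c.items()):
            card[f"c{i}{j}"] = v
        for k, v in enumerate(self.mu, 1):
            card[f"mu{k}"] = v
        for k, v in enumerate(self.alpha, 1):
            card[f"alpha{k}"] = v
        for k, v in enumerate(self.d, 1):
            card[f"d{k}"] = v
        if self.E is not None:
            card["E"] = self.E
        if self.nu is not None:
            card["nu"] = self.nu
        return card

    @classmethod
    def from_card(cls, card: Mapping) -> "HyperelasticMaterial":
        c = {}
        mu: dict[int, float] = {}
        alpha: dict[int, float] = {}
        d: dict[int, float] = {}
        for key, val in card.items():
            if key in ("label", "family", "order", "E", "nu"):
                continue
            if key.startswith("mu"):
                mu[int(key[2:])] = float(val)
            elif key.startswith("alpha"):
                alpha[int(key[5:])] = float(val)
            elif key.startswith("d"):
                d[int(key[1:])] = float(val)
            elif key.startswith("c") and len(key) == 3:
                c[(int(key[1]), int(key[2]))] = float(val)
            else:
                raise ConfigurationError(f"unrecognized card key {key!r}")
        return cls(
            family=card["family"],
            order=int(card.get("order", max(len(mu), 1) if mu else 1)),
            c=c,
            mu=tuple(mu[k] for k in sorted(mu)),
            alpha=tuple(alpha[k] for k in sorted(alpha)),
            d=tuple(d[k] for k in sorted(d)),
            E=card.get("E"),
            nu=card.get("nu"),
            label=card.get("label", ""),
        )

    # -- thin method wrappers ---------------------------------------------

    def energy(self, stretches: Sequence[float]) -> float:
        return strain_energy(self, stretches)

    def stress(self, mode: str, stretch):
        return nominal_stress(self, mode, stretch)

    def mu0(self) -> float:
        return initial_shear_modulus(self)


# -- convenience constructors ---------------------------------------------


def neo_hookean(c10: float, label: str = "") -> HyperelasticMaterial:
    return HyperelasticMaterial("neo_hookean", 1, {(1, 0): c10}, label=label)


def mooney_rivlin(c10: float, c01: float, label: str = "") -> HyperelasticMaterial:
    return HyperelasticMaterial("mooney_rivlin", 1, {(1, 0): c10, (0, 1): c01}, label=label)


def yeoh(c10: float, c20: float, c30: float, label: str = "") -> HyperelasticMaterial:
    return HyperelasticMaterial("yeoh", 3, {(1, 0): c10, (2, 0): c20, (3, 0): c30}, label=label)


def reduced_polynomial(coeffs: Sequence[float], label: str = "") -> HyperelasticMaterial:
    c = {(i + 1, 0): v for i, v in enumerate(coeffs)}
    return HyperelasticMaterial("reduced_polynomial", len(coeffs), c, label=label)


def polynomial(c: Mapping[tuple[int, int], float], order: int, label: str = "") -> HyperelasticMaterial:
    return HyperelasticMaterial("polynomial", order, c, label=label)


def ogden(
    mu: Sequence[float], alpha: Sequence[float], d: Sequence[float] = (), label: str = ""
) -> HyperelasticMaterial:
    return HyperelasticMaterial(
        "ogden", len(tuple(mu)), mu=tuple(mu), alpha=tuple(alpha), d=tuple(d), label=label
    )


def linear_elastic(E: float, nu: float, label: str = "") -> HyperelasticMaterial:
    return HyperelasticMaterial("linear_elastic", 1, E=E, nu=nu, label=label)


# -- strain energy ---------------------------------------------------------


def strain_energy(material: HyperelasticMaterial, stretches: Sequence[float]) -> float:
    """Strain energy density (MPa) at the given principal stretches.

    The evaluation path is incompressible: the product of the stretches must
    be 1 to within 1e-9 and the invariants are the deviatoric ones evaluated
    at unit Jacobian.
    """
    l1, l2, l3 = (float(s) for s in stretches)
    if min(l1, l2, l3) <= 0:
        raise ValueError("principal stretches must be positive")
    if abs(l1 * l2 * l3 - 1.0) > _INCOMP_TOL:
        raise ValueError("stretches violate incompressibility (l1*l2*l3 != 1)")
    if material.family == "linear_elastic":
        raise ConfigurationError("linear_elastic has no hyperelastic energy")
    if material.family == "ogden":
        u = 0.0
        for m, a in zip(material.mu, material.alpha):
            u += 2.0 * m / a**2 * (l1**a + l2**a + l3**a - 3.0)
        return u
    i1 = l1 * l1 + l2 * l2 + l3 * l3
    i2 = l1**-2 + l2**-2 + l3**-2
    u = 0.0
    for (i, j), cij in material.c.items():
        u += cij * (i1 - 3.0) ** i * (i2 - 3.0) ** j
    return u


# -- nominal stress --------------------------------------------------------


def _dU_dI(material: HyperelasticMaterial, i1, i2):
    """Partial derivatives of the invariant-based energy at (i1, i2)."""
    dU1 = np.zeros_like(np.asarray(i1, dtype=float))
    dU2 = np.zeros_like(dU1)
    for (i, j), cij in material.c.items():
        if i > 0:
            dU1 = dU1 + cij * i * (i1 - 3.0) ** (i - 1) * (i2 - 3.0) ** j
        if j > 0:
            dU2 = dU2 + cij * j * (i1 - 3.0) ** i * (i2 - 3.0) ** (j - 1)
    return dU1, dU2


def nominal_stress(material: HyperelasticMaterial, mode: str, stretch):
    """Per-axis nominal (engineering) stress (MPa) in a homogeneous test mode.

    ``stretch`` may be a scalar or array of principal stretches along the
    loading axis.  Zero at the reference state cancels analytically: every
    closed form carries an explicit ``(l^p - l^q)`` factor.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if material.family == "linear_elastic":
        raise ConfigurationError("nominal_stress is undefined for linear_elastic")
    lam = np.asarray(stretch, dtype=float)
    scalar = lam.ndim == 0
    lam = np.atleast_1d(lam)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")

    if material.family == "ogden":
        # transverse exponent of the mode path: uniaxial l2=l^-1/2,
        # equibiaxial l3=l^-2, planar l3=l^-1
        q = {"uniaxial": -0.5, "equibiaxial": -2.0, "planar": -1.0}[mode]
        P = np.zeros_like(lam)
        for m, a in zip(material.mu, material.alpha):
            P += 2.0 * m / a * (lam ** (a - 1.0) - lam ** (q * a - 1.0))
    else:
        if mode == "uniaxial":
            i1 = lam**2 + 2.0 / lam
            i2 = 2.0 * lam + lam**-2
            f = 2.0 * (lam - lam**-2)
            g = 1.0 / lam
        elif mode == "equibiaxial":
            i1 = 2.0 * lam**2 + lam**-4
            i2 = lam**4 + 2.0 * lam**-2
            f = 2.0 * (lam - lam**-5)
            g = lam**2
        else:  # planar
            i1 = lam**2 + 1.0 + lam**-2
            i2 = i1
            f = 2.0 * (lam - lam**-3)
            g = np.ones_like(lam)
        dU1, dU2 = _dU_dI(material, i1, i2)
        P = f * (dU1 + g * dU2)
    return float(P[0]) if scalar else P


# -- initial shear modulus -------------------------------------------------


def initial_shear_modulus(material: HyperelasticMaterial) -> float:
    """Small-strain shear modulus mu0 (MPa) implied by the parameter set.

    Polynomial-type: ``2 (C10 + C01)``; reduced polynomial (incl. neo-Hookean,
    Yeoh): ``2 C10``; Ogden: ``(1/2) sum mu_i alpha_i``; Hookean:
    ``E / (2 (1 + nu))``.
    """
    fam = material.family
    if fam == "linear_elastic":
        return material.E / (2.0 * (1.0 + material.nu))
    if fam == "ogden":
        return 0.5 * sum(m * a for m, a in zip(material.mu, material.alpha))
    c10 = material.c.get((1, 0), 0.0)
    c01 = material.c.get((0, 1), 0.0)
    return 2.0 * (c10 + c01)


def tangent_shear_modulus(material: HyperelasticMaterial) -> float:
    """True small-strain shear modulus of the implemented energy (MPa).

    For the invariant-based families and the Hookean solid this coincides
    with :func:`initial_shear_modulus`.  For the Ogden form used here
    (``2 mu_i / alpha_i^2`` prefactor) the tangent at the reference state is
    ``sum mu_i``: the conventional reporting formula ``(1/2) sum mu_i
    alpha_i`` belongs to the classical Ogden prefactor and overstates the
    tangent stiffness whenever ``alpha_i != 2``.  The uniaxial stress slope
    at ``lambda = 1`` is ``3 *`` this value (incompressible Young's modulus).
    """
    if material.family == "ogden":
        return float(sum(material.mu))
    return initial_shear_modulus(material)


# -- Drucker stability -----------------------------------------------------


@dataclass(frozen=True)
class StabilityReport:
    """Per-mode monotonicity verdicts of a stretch-sweep Drucker screen.

    ``verdicts`` maps ``(mode, branch)`` with branch in {"tension",
    "compression"} to a bool; ``first_unstable`` records, for each failing
    mode, the first grid stretch at which nominal stress fails to increase.
    """

    stable: bool
    verdicts: Mapping[tuple[str, str], bool]
    first_unstable: Mapping[tuple[str, str], float]
    stretch_min: float
    stretch_max: float
    step: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "verdicts", dict(self.verdicts))
        object.__setattr__(self, "first_unstable", dict(self.first_unstable))
        if self.stable != all(self.verdicts.values()):
            raise ConfigurationError("overall verdict must equal conjunction of modes")


def drucker_stability(
    material: HyperelasticMaterial,
    stretch_min: float = 0.5,
    stretch_max: float = 2.0,
    step: float = 0.005,
) -> StabilityReport:
    """Screen a material for Drucker stability by stretch sweeps.

    The criterion applied is that nominal stress must strictly increase with
    stretch in each of the three homogeneous modes, checked separately on the
    compressive (``stretch < 1``) and tensile (``stretch > 1``) branches of a
    uniform grid.
    """
    if not (0 < stretch_min < 1 < stretch_max):
        raise ConfigurationError("need 0 < stretch_min < 1 < stretch_max")
    if step <= 0:
        raise ConfigurationError("step must be positive")
    n = int(round((stretch_max - stretch_min) / step)) + 1
    if n < 3:
        raise ConfigurationError("degenerate sweep grid (fewer than 3 points)")
    grid = stretch_min + step * np.arange(n)
    grid = np.unique(np.clip(np.append(grid, 1.0), stretch_min, stretch_max))

    verdicts: dict[tuple[str, str], bool] = {}
    first: dict[tuple[str, str], float] = {}
    for mode in MODES:
        P = nominal_stress(material, mode, grid)
        increasing = np.diff(P) > 0.0
        for branch, mask in (
            ("compression", grid[:-1] < 1.0),
            ("tension", grid[:-1] >= 1.0),
        ):
            ok = bool(np.all(increasing[mask]))
            verdicts[(mode, branch)] = ok
            if not ok:
                bad = np.where(mask & ~increasing)[0]
                first[(mode, branch)] = float(grid[bad[0]])
    return StabilityReport(
        stable=all(verdicts.values()),
        verdicts=verdicts,
        first_unstable=first,
        stretch_min=stretch_min,
        stretch_max=stretch_max,
        step=step,
    )
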