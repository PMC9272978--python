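"""Calibration of hyperelastic models to uniaxial compression tests.

Raw force-displacement records are converted to engineering stress-strain
(``sigma = F/A``, ``eps = dL/L0``, both stored as magnitudes), decimated with
the two-interval sampling rule, and fitted by least squares.  Models linear
in their coefficients (all the invariant-based families) are solved exactly;
the Ogden family is solved by bounded nonlinear least squares with a
multi-start over the exponent.  Fit quality is the squared Pearson
correlation between observed and model stresses — a correlation measure, not
``1 - SSE/SST``.

Compression is handled through the stretch ``lambda = 1 - eps``; model
stresses along the compression branch are negative, and fitting is performed
on their magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constitutive import (
    HyperelasticMaterial,
    StabilityReport,
    drucker_stability,
    nominal_stress,
    ogden,
)

__all__ = [
    "TestCurve",
    "FitResult",
    "CompositionSummary",
    "engineering_stress_strain",
    "smooth_subsample",
    "fit_model",
    "r_squared",
    "aggregate_parameters",
    "density_from_geometry",
]

LINEAR_FAMILIES = ("neo_hookean", "mooney_rivlin", "polynomial", "reduced_polynomial", "yeoh")


@dataclass(frozen=True)
class TestCurve:
    """One compression test as ascending (strain, stress) magnitudes.

    Strains are dimensionless engineering strains in roughly [0, 0.5];
    stresses are engineering stress magnitudes in MPa.  The first point must
    sit at the origin (the anchoring is done upstream).
    """

    __test__ = False  # not a pytest class despite the name

    strain: np.ndarray
    stress: np.ndarray
    sample_id: str = ""
    composition: str = ""
    area_mm2: float | None = None
    initial_height_mm: float | None = None

    def __post_init__(self) -> None:
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)
        if strain.ndim != 1 or strain.shape != stress.shape:
            raise ValueError("strain and stress must be 1-D and of equal length")
        if strain.size < 2:
            raise ValueError("a curve needs at least 2 points")
        if not (np.all(np.isfinite(strain)) and np.all(np.isfinite(stress))):
            raise ValueError("non-finite values in curve")
        if np.any(strain < 0) or np.any(stress < 0):
            raise ValueError("curves store magnitudes; negative values found")
        if np.any(np.diff(strain) <= 0):
            raise ValueError("strain must be strictly increasing")
        if strain[0] > 1e-9:
            raise ValueError("curve must start at zero strain")

    def __len__(self) -> int:
        return int(self.strain.size)


@dataclass(frozen=True)
class FitResult:
    """Fitted material plus fit quality and stability for one sample."""

    material: HyperelasticMaterial
    r_squared: float
    stability: StabilityReport | None
    residual_norm: float
    converged: bool
    sample_id: str = ""
    composition: str = ""
    n_points: int = 0
    restarts_used: int = 0
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CompositionSummary:
    """Per-composition mean +/- SD of fitted coefficients."""

    composition: str
    family: str
    mean: Mapping[str, float]
    sd: Mapping[str, float]
    n_included: int
    n_excluded: int
    excluded: Mapping[str, str]  # sample_id -> reason
    mean_material: HyperelasticMaterial

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", dict(self.mean))
        object.__setattr__(self, "sd", dict(self.sd))
        object.__setattr__(self, "excluded", dict(self.excluded))
        if any(v < 0 for v in self.sd.values()):
            raise ValueError("SDs must be nonnegative")


# -- raw conversion --------------------------------------------------------


def engineering_stress_strain(
    force_N: Sequence[float],
    displacement_mm: Sequence[float],
    area_mm2: float,
    initial_height_mm: float,
    sample_id: str = "",
    composition: str = "",
) -> TestCurve:
    """Convert force (N) and crosshead displacement (mm) to a TestCurve.

    Stress is ``|F|/A`` in MPa (N/mm^2), strain ``|dL|/L0``; the curve is
    anchored so that it starts at (0, 0).
    """
    if area_mm2 <= 0 or initial_height_mm <= 0:
        raise ValueError("area and initial height must be positive")
    F = np.abs(np.asarray(force_N, dtype=float))
    dL = np.abs(np.asarray(displacement_mm, dtype=float))
    if F.shape != dL.shape:
        raise ValueError("force and displacement series differ in length")
    strain = dL / initial_height_mm
    stress = F / area_mm2
    strain = strain - strain[0]
    stress = np.clip(stress - stress[0], 0.0, None)
    return TestCurve(strain, stress, sample_id, composition, area_mm2, initial_height_mm)


def smooth_subsample(
    curve: TestCurve,
    interval_low: int = 40,
    interval_high: int = 20,
    breakpoint: float = 0.25,
) -> TestCurve:
    """Decimate a curve with the two-interval sampling rule.

    Every ``interval_low``-th point is kept below the strain breakpoint and
    every ``interval_high``-th point at or above it (counted from the first
    point of each region); the first and last points are always retained.
    This is pure index decimation, denser above the breakpoint to weight the
    strain-stiffening toe of the curve.
    """
    if interval_low < 1 or interval_high < 1:
        raise ValueError("intervals must be >= 1")
    low = np.flatnonzero(curve.strain < breakpoint)
    high = np.flatnonzero(curve.strain >= breakpoint)
    keep = set(low[::interval_low]) | set(high[::interval_high]) | {0, len(curve) - 1}
    idx = np.array(sorted(keep), dtype=int)
    if idx.size < 2:
        raise ValueError("fewer than 2 points after subsampling")
    return TestCurve(
        curve.strain[idx],
        curve.stress[idx],
        curve.sample_id,
        curve.composition,
        curve.area_mm2,
        curve.initial_height_mm,
    )


# -- fit quality -----------------------------------------------------------


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Squared Pearson correlation between observed and model stresses."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if obs.size < 3:
        raise ValueError("need at least 3 points")
    so = obs - obs.mean()
    sp = pred - pred.mean()
    denom = np.sqrt((so**2).sum() * (sp**2).sum())
    if denom == 0.0:
        raise ValueError("constant series: correlation undefined")
    return float(((so * sp).sum() / denom) ** 2)


# -- model fitting ---------------------------------------------------------


def _linear_basis(family: str, order: int, lam: np.ndarray) -> tuple[np.ndarray, list]:
    """Columns of |uniaxial stress| per unit coefficient, compression branch.

    The uniaxial nominal stress of every invariant-based family is linear in
    the C_ij; on the compression branch (lam < 1) the stress is negative, so
    the magnitude design matrix is built from -P per coefficient.
    """
    from .constitutive import _poly_terms

    if family == "neo_hookean":
        terms = [(1, 0)]
    elif family == "mooney_rivlin":
        terms = [(1, 0), (0, 1)]
    elif family == "yeoh":
        terms = [(1, 0), (2, 0), (3, 0)]
    elif family == "reduced_polynomial":
        terms = [(i, 0) for i in range(1, order + 1)]
    elif family == "polynomial":
        terms = _poly_terms(order)
    else:
        raise ValueError(f"not a linear family: {family}")
    i1 = lam**2 + 2.0 / lam
    i2 = 2.0 * lam + lam**-2
    f = 2.0 * (lam - lam**-2)
    cols = []
    for i, j in terms:
        dU1 = i * (i1 - 3.0) ** (i - 1) * (i2 - 3.0) ** j if i > 0 else 0.0
        dU2 = j * (i1 - 3.0) ** i * (i2 - 3.0) ** (j - 1) if j > 0 else 0.0
        cols.append(-f * (dU1 + dU2 / lam))
    return np.column_stack(cols), terms


def _build_material(family: str, order: int, terms, coeffs) -> HyperelasticMaterial:
    c = {t: float(v) for t, v in zip(terms, coeffs)}
    fam_order = {"neo_hookean": 1, "mooney_rivlin": 1, "yeoh": 3}.get(family, order)
    return HyperelasticMaterial(family, fam_order, c)


def _small_strain_mu0(curve: TestCurve, strain_limit: float = 0.05) -> float:
    """mu0 estimate from the initial slope (incompressible E = 3 mu0)."""
    m = curve.strain < strain_limit
    if m.sum() >= 3:
        slope = np.polyfit(curve.strain[m], curve.stress[m], 1)[0]
    else:
        slope = curve.stress[1] / max(curve.strain[1], 1e-12)
    return max(float(slope) / 3.0, 1e-6)


def fit_model(
    curve: TestCurve,
    family: str,
    order: int = 1,
    stability_sweep: tuple[float, float, float] = (0.5, 2.0, 0.005),
    alpha_branch: str = "positive",
    mu_bounds: tuple[float, float] = (0.0, 10.0),
    alpha_bounds: tuple[float, float] = (0.0, 50.0),
) -> FitResult:
    """Least-squares fit of one constitutive family to one compression curve.

    Invariant-based families are solved as (exact) linear least squares;
    first-order Ogden by bounded nonlinear least squares, multi-started over
    ``alpha1 in {2, 4, 6, 8, 10, 12}`` with ``mu1`` seeded from the
    small-strain modulus.  ``alpha_branch="negative"`` exposes the mirrored
    ``alpha1 < 0`` solution branch, which is otherwise excluded.

    Degenerate inputs (all-zero stress) and rank-deficient linear systems are
    flagged on the result, not raised.
    """
    lam = 1.0 - curve.strain
    if np.any(lam <= 0):
        raise ValueError("strains >= 1 are outside the compressive stretch range")
    obs = curve.stress
    flags: list[str] = []

    if not np.any(obs > 0):
        mat = _build_material("neo_hookean", 1, [(1, 0)], [0.0]) if family != "ogden" else ogden([1e-9], [2.0])
        return FitResult(mat, float("nan"), None, 0.0, False, curve.sample_id,
                         curve.composition, len(curve), 0, ("degenerate",))

    if family in LINEAR_FAMILIES:
        X, terms = _linear_basis(family, order, lam)
        if len(curve) < len(terms) + 1:
            raise ValueError("curve has fewer points than coefficients + 1")
        coeffs, _, rank, sv = np.linalg.lstsq(X, obs, rcond=None)
        if rank < len(terms):
            flags.append(f"rank_deficient(rank={rank}, cond=inf)")
        elif sv[0] / sv[-1] > 1e10:
            flags.append(f"ill_conditioned(cond={sv[0] / sv[-1]:.2e})")
        material = _build_material(family, order, terms, coeffs)
        pred = np.abs(nominal_stress(material, "uniaxial", lam))
        restarts = 0
        converged = True
    elif family == "ogden":
        if len(curve) < 3:
            raise ValueError("curve has fewer points than coefficients + 1")
        mu0_hat = _small_strain_mu0(curve)
        sign = 1.0 if alpha_branch == "positive" else -1.0
        lo = (max(mu_bounds[0], 1e-9), sign * alpha_bounds[1] if sign < 0 else max(alpha_bounds[0], 1e-9))
        hi = (mu_bounds[1], -1e-9 if sign < 0 else alpha_bounds[1])
        if sign < 0:
            lo = (max(mu_bounds[0], 1e-9), -alpha_bounds[1])

        def resid(x):
            m, a = x
            return np.abs(2.0 * m / a * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))) - obs

        best = None
        restarts = 0
        for a0 in (2.0, 4.0, 6.0, 8.0, 10.0, 12.0):
            a0 = sign * a0
            m0 = min(max(2.0 * mu0_hat / abs(a0), 1e-6), mu_bounds[1] * 0.999)
            sol = least_squares(resid, x0=[m0, a0], bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            restarts += 1
            if best is None or sol.cost < best.cost:
                best = sol
        material = ogden([float(best.x[0])], [float(best.x[1])])
        pred = np.abs(nominal_stress(material, "uniaxial", lam))
        converged = bool(best.success)
        if not converged:
            flags.append("non_convergent")
    else:
        raise ValueError(f"unsupported family {family!r}")

    try:
        r2 = r_squared(obs, pred)
    except ValueError:
        r2 = float("nan")
        flags.append("r2_undefined")
    stab = drucker_stability(material, *stability_sweep)
    if not stab.stable:
        flags.append("unstable")
    return FitResult(
        material=material,
        r_squared=r2,
        stability=stab,
        residual_norm=float(np.linalg.norm(obs - pred)),
        converged=converged,
        sample_id=curve.sample_id,
        composition=curve.composition,
        n_points=len(curve),
        restarts_used=restarts,
        flags=tuple(flags),
    )


# -- aggregation -----------------------------------------------------------


def _coeff_dict(material: HyperelasticMaterial) -> dict[str, float]:
    out = {f"c{i}{j}": v for (i, j), v in sorted(material.c.items())}
    for k, v in enumerate(material.mu, 1):
        out[f"mu{k}"] = v
    for k, v in enumerate(material.alpha, 1):
        out[f"alpha{k}"] = v
    return out


def aggregate_parameters(
    fits: Sequence[FitResult],
    exclude_negative_alpha: bool = True,
    exclude_ids: Sequence[str] = (),
) -> CompositionSummary:
    """Mean +/- SD of fitted coefficients across samples of one composition.

    Ogden fits with ``alpha1 < 0`` are excluded (the mirrored solution branch
    cannot be averaged with the positive branch); ``exclude_ids`` lets the
    caller drop the same samples from other-family aggregations so that all
    families are summarized over an identical sample set.  SDs are population
    SDs over the included samples (ddof=0 for n=1, else ddof=1).
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    family = fits[0].material.family
    if any(f.material.family != family for f in fits):
        raise ValueError("fits mix families")
    excluded: dict[str, str] = {}
    included: list[FitResult] = []
    for k, f in enumerate(fits):
        sid = f.sample_id or f"sample{k}"
        if sid in set(exclude_ids):
            excluded[sid] = "excluded_by_caller"
        elif "degenerate" in f.flags:
            excluded[sid] = "degenerate"
        elif exclude_negative_alpha and family == "ogden" and f.material.alpha[0] < 0:
            excluded[sid] = "alpha1 < 0"
        else:
            included.append(f)
    if not included:
        raise ValueError("all samples excluded; nothing to aggregate")

    names = list(_coeff_dict(included[0].material))
    table = np.array([[_coeff_dict(f.material)[n] for n in names] for f in included])
    mean = {n: float(m) for n, m in zip(names, table.mean(axis=0))}
    ddof = 1 if len(included) > 1 else 0
    sd = {n: float(s) for n, s in zip(names, table.std(axis=0, ddof=ddof))}

    proto = included[0].material
    if family == "ogden":
        mean_mat = ogden(
            [mean[f"mu{k}"] for k in range(1, proto.order + 1)],
            [mean[f"alpha{k}"] for k in range(1, proto.order + 1)],
        )
    else:
        c = {(i, j): mean[f"c{i}{j}"] for (i, j) in proto.c}
        mean_mat = HyperelasticMaterial(family, proto.order, c)
    composition = included[0].composition
    return CompositionSummary(
        composition=composition,
        family=family,
        mean=mean,
        sd=sd,
        n_included=len(included),
        n_excluded=len(excluded),
        excluded=excluded,
        mean_material=mean_mat,
    )


# -- density ---------------------------------------------------------------


def density_from_geometry(mass_g: float, diameter_mm: float, height_mm: float) -> float:
    """Density in kg m^-3 of a cylindrical sample, rho = 4 m / (pi d^2 L)."""
    if mass_g <= 0 or diameter_mm <= 0 or height_mm <= 0:
        raise ValueError("mass, diameter and height must be positive")
    rho_g_mm3 = 4.0 * mass_g / (np.pi * diameter_mm**2 * height_mm)
    return rho_g_mm3 * 1e6
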