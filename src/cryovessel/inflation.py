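"""Quasi-static inflation of an N-layer incompressible hyperelastic tube.

The vessel is a straight, axially constrained (``lambda_z = 1``) thick-walled
cylinder of bonded concentric hyperelastic layers under internal pressure,
optionally supported on the outside by a linearly elastic annulus of
surrounding soft tissue.  With incompressibility and a fixed axial stretch
the kinematics collapse to one scalar unknown, the deformed luminal radius
``r_i``:

    r(R)^2 = R^2 - R_i^2 + r_i^2,   lam_th = r/R,   lam_r = 1/lam_th

Each material point deforms along the planar (pure-shear) path
``(1/lam, lam, 1)``, so the through-wall stress difference is
``sig_th - sig_r = lam * W'(lam)`` with ``W(lam) = U(1/lam, lam, 1)``, i.e.
``lam`` times the planar nominal stress.  Radial equilibrium
``d sig_r / dr = (sig_th - sig_r)/r`` integrates to the pressure balance

    P_in - P_out(r_i) = integral_{r_i}^{r_o} (sig_th - sig_r) dr / r

whose root in ``r_i`` is found by bracketing + Brent's method; the radial
stress profile is then recovered by quadrature from the lumen outward and
``sig_th = sig_r + lam * W'(lam)``.  Pressures are supplied in mmHg and
converted at 133.322 Pa/mmHg.

The unloaded luminal radius is never a measured quantity here; the default
of 1.5 mm is a coronary-scale assumption and is echoed in every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .constitutive import HyperelasticMaterial, drucker_stability, nominal_stress
from .fixtures import MMHG_TO_MPA

__all__ = [
    "ExternalBC",
    "traction_free",
    "constant_pressure",
    "elastic_foundation",
    "Layer",
    "VesselConfig",
    "TransmuralProfile",
    "InflationResult",
    "foundation_stiffness",
    "inflate",
    "pressure_sweep",
    "compliance",
    "ConvergenceError",
]

LAYER_LABELS = ("intima", "media", "adventitia")


class ConvergenceError(RuntimeError):
    """The equilibrium root could not be bracketed or resolved."""


@dataclass(frozen=True)
class ExternalBC:
    """Outer-surface boundary condition.

    ``kind`` is one of ``traction_free``, ``constant_pressure`` (``P_o`` in
    MPa) or ``elastic_foundation`` (plane-strain Hookean annulus with a fixed
    outer surface; ``outer_radius_mm=None`` means 5x the vessel outer
    radius).
    """

    kind: str = "traction_free"
    P_o_MPa: float = 0.0
    E_MPa: float = 0.0
    nu: float = 0.0
    outer_radius_mm: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("traction_free", "constant_pressure", "elastic_foundation"):
            raise ValueError(f"unknown external BC {self.kind!r}")
        if self.kind == "elastic_foundation" and not (self.E_MPa >= 0 and 0 < self.nu < 0.5):
            raise ValueError("elastic foundation needs E >= 0 and 0 < nu < 0.5")


def traction_free() -> ExternalBC:
    return ExternalBC("traction_free")


def constant_pressure(P_o_MPa: float) -> ExternalBC:
    return ExternalBC("constant_pressure", P_o_MPa=P_o_MPa)


def elastic_foundation(E_MPa: float = 0.05, nu: float = 0.49, outer_radius_mm: float | None = None) -> ExternalBC:
    return ExternalBC("elastic_foundation", E_MPa=E_MPa, nu=nu, outer_radius_mm=outer_radius_mm)


@dataclass(frozen=True)
class Layer:
    thickness_mm: float
    material: HyperelasticMaterial
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("layer thickness must be positive")


@dataclass(frozen=True)
class VesselConfig:
    """Unloaded geometry, layer materials and external support of a vessel."""

    luminal_radius_mm: float = 1.5
    layers: tuple[Layer, ...] = ()
    external_bc: ExternalBC = field(default_factory=elastic_foundation)
    name: str = ""
    #: stretch range over which every layer material must be Drucker-stable
    stability_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.luminal_radius_mm <= 0:
            raise ValueError("luminal radius must be positive")
        if not self.layers:
            raise ValueError("vessel needs at least one layer")
        for lay in self.layers:
            rep = drucker_stability(lay.material, *self.stability_range, 0.005)
            if not rep.stable:
                raise ValueError(
                    f"layer {lay.label!r} material is Drucker-unstable over "
                    f"{self.stability_range}: {rep.first_unstable}"
                )
        bc = self.external_bc
        if bc.kind == "elastic_foundation" and bc.outer_radius_mm is not None:
            if bc.outer_radius_mm <= self.outer_radius_mm:
                raise ValueError("foundation outer radius must exceed vessel outer radius")

    @property
    def interface_radii_mm(self) -> np.ndarray:
        """Reference radii of all layer boundaries, lumen to outer surface."""
        return self.luminal_radius_mm + np.concatenate(
            ([0.0], np.cumsum([lay.thickness_mm for lay in self.layers]))
        )

    @property
    def outer_radius_mm(self) -> float:
        return float(self.interface_radii_mm[-1])


@dataclass(frozen=True)
class TransmuralProfile:
    """Sampled through-wall fields at one luminal pressure.

    Stresses are Cauchy stresses in MPa with their mechanical sign
    (``sigma_r <= 0`` under inflation); strains are reported as magnitudes
    (``eps_theta = lam_th - 1 >= 0``, ``eps_r = |lam_r - 1|``), with the
    signed radial strain available as ``-eps_r``.
    """

    R_mm: np.ndarray
    r_mm: np.ndarray
    layer: np.ndarray  # layer label per sample
    sigma_theta: np.ndarray
    sigma_r: np.ndarray
    eps_theta: np.ndarray
    eps_r: np.ndarray
    pressure_mmHg: float

    @property
    def pressure_MPa(self) -> float:
        return self.pressure_mmHg * MMHG_TO_MPA

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "R_mm": self.R_mm,
                "r_mm": self.r_mm,
                "layer": self.layer,
                "sigma_theta_MPa": self.sigma_theta,
                "sigma_r_MPa": self.sigma_r,
                "eps_theta": self.eps_theta,
                "eps_r": self.eps_r,
            }
        )

    def layer_stats(self) -> pd.DataFrame:
        """Unweighted per-layer mean and spatial SD of each field."""
        df = self.to_frame()
        g = df.groupby("layer", sort=False)[
            ["sigma_theta_MPa", "sigma_r_MPa", "eps_theta", "eps_r"]
        ]
        out = g.agg(["mean", "std"])
        out.columns = ["_".join(c) for c in out.columns]
        return out.reset_index()

    def interface_jumps(self) -> list[dict]:
        """Stress jumps at internal layer interfaces (outer minus inner side)."""
        jumps = []
        labels = list(dict.fromkeys(self.layer))
        for a, b in zip(labels[:-1], labels[1:]):
            i = np.flatnonzero(self.layer == a)[-1]
            j = np.flatnonzero(self.layer == b)[0]
            jumps.append(
                {
                    "interface": f"{a}-{b}",
                    "R_mm": float(self.R_mm[j]),
                    "sigma_theta_jump_MPa": float(self.sigma_theta[j] - self.sigma_theta[i]),
                    "sigma_r_jump_MPa": float(self.sigma_r[j] - self.sigma_r[i]),
                }
            )
        return jumps


@dataclass(frozen=True)
class InflationResult:
    profile: TransmuralProfile
    luminal_radius_deformed_mm: float
    residual_MPa: float
    iterations: int
    vessel: VesselConfig
    assumed_luminal_radius_mm: float = 1.5


# -- elastic foundation ----------------------------------------------------


def foundation_stiffness(E_MPa: float, nu: float, inner_radius_mm: float, outer_radius_mm: float) -> float:
    """Radial stiffness (MPa/mm) of a plane-strain annulus, fixed outer face.

    From the Lame solution ``u = A r + B / r`` with ``u(b) = 0`` and inner
    pressure ``q`` at ``r = a``:

        k = q / u(a) = 2 a (lam + G + G b^2/a^2) / (b^2 - a^2)

    with Lame constants ``lam`` and ``G``.  For ``b -> inf`` this tends to
    the infinite-medium value ``2 G / a``; for ``E -> 0`` it vanishes
    (traction-free recovered).
    """
    if not (outer_radius_mm > inner_radius_mm > 0):
        raise ValueError("need outer_radius > inner_radius > 0")
    if not (0 < nu < 0.5):
        raise ValueError("need 0 < nu < 0.5")
    a, b = inner_radius_mm, outer_radius_mm
    G = E_MPa / (2.0 * (1.0 + nu))
    lame = E_MPa * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return 2.0 * a * (lame + G + G * b * b / (a * a)) / (b * b - a * a)


# -- inflation solver ------------------------------------------------------


def _hoop_minus_radial(material: HyperelasticMaterial, lam_th):
    """sig_th - sig_r = lam_th * planar nominal stress at lam_th."""
    return lam_th * nominal_stress(material, "planar", lam_th)


def _wall_integral(vessel: VesselConfig, c: float, epsrel: float) -> float:
    """integral over the wall of (sig_th - sig_r)/r dr, as integral over R.

    With r^2 = R^2 + c and r dr = R dR the integrand reduces to
    planar_stress(lam_th) / r(R).
    """
    total = 0.0
    radii = vessel.interface_radii_mm
    for j, lay in enumerate(vessel.layers):

        def f(R, mat=lay.material):
            r = np.sqrt(R * R + c)
            return nominal_stress(mat, "planar", r / R) / r

        val, _ = quad(f, radii[j], radii[j + 1], epsabs=1e-13, epsrel=epsrel, limit=200)
        total += val
    return total


def _external_pressure(vessel: VesselConfig, c: float) -> float:
    bc = vessel.external_bc
    if bc.kind == "traction_free":
        return 0.0
    if bc.kind == "constant_pressure":
        return bc.P_o_MPa
    Ro = vessel.outer_radius_mm
    b = bc.outer_radius_mm if bc.outer_radius_mm is not None else 5.0 * Ro
    k = foundation_stiffness(bc.E_MPa, bc.nu, Ro, b) if bc.E_MPa > 0 else 0.0
    ro = np.sqrt(Ro * Ro + c)
    return k * (ro - Ro)


def inflate(
    vessel: VesselConfig,
    pressure_mmHg: float,
    samples_per_layer: int = 64,
    quad_epsrel: float = 1e-9,
    root_tol_MPa: float = 1e-10,
) -> InflationResult:
    """Solve the inflation boundary-value problem at one luminal pressure."""
    if pressure_mmHg < 0:
        raise ValueError("pressure must be nonnegative")
    if samples_per_layer < 2:
        raise ValueError("need at least 2 samples per layer")
    P = pressure_mmHg * MMHG_TO_MPA
    Ri = vessel.luminal_radius_mm
    iters = 0

    def residual(ri: float) -> float:
        nonlocal iters
        iters += 1
        cc = ri * ri - Ri * Ri
        return P - _external_pressure(vessel, cc) - _wall_integral(vessel, cc, quad_epsrel)

    if P == 0.0:
        ri = Ri
        res = 0.0
    else:
        lo = Ri
        hi = Ri * 1.001
        f_hi = residual(hi)
        n_expand = 0
        while f_hi > 0:
            hi *= 1.05
            f_hi = residual(hi)
            n_expand += 1
            if n_expand > 200:
                raise ConvergenceError(
                    f"no equilibrium in bracket [{Ri}, {hi}] mm at "
                    f"{pressure_mmHg} mmHg (limit-point inflation or material too soft)"
                )
        ri = brentq(residual, lo, hi, xtol=1e-13, rtol=8.9e-16)
        res = residual(ri)
        if abs(res) > root_tol_MPa:
            raise ConvergenceError(f"equilibrium residual {res:.3e} MPa exceeds tolerance")

    profile = _build_profile(vessel, ri, pressure_mmHg, samples_per_layer, quad_epsrel)
    return InflationResult(
        profile=profile,
        luminal_radius_deformed_mm=float(ri),
        residual_MPa=float(res),
        iterations=iters,
        vessel=vessel,
        assumed_luminal_radius_mm=Ri,
    )


def _build_profile(
    vessel: VesselConfig, ri: float, pressure_mmHg: float, n: int, epsrel: float
) -> TransmuralProfile:
    P = pressure_mmHg * MMHG_TO_MPA
    Ri = vessel.luminal_radius_mm
    c = ri * ri - Ri * Ri
    radii = vessel.interface_radii_mm

    R_all, r_all, lab_all, st_all, sr_all = [], [], [], [], []
    sig_r = -P
    for j, lay in enumerate(vessel.layers):
        Rg = np.linspace(radii[j], radii[j + 1], n)
        mat = lay.material

        def f(R):
            r = np.sqrt(R * R + c)
            return nominal_stress(mat, "planar", r / R) / r

        for idx, R in enumerate(Rg):
            if not (j == 0 and idx == 0):
                R_prev = R_all[-1]
                seg, _ = quad(f, R_prev, R, epsabs=1e-13, epsrel=epsrel, limit=200)
                sig_r = sr_all[-1] + seg
            r = float(np.sqrt(R * R + c))
            lam = r / R
            R_all.append(float(R))
            r_all.append(r)
            lab_all.append(lay.label)
            sr_all.append(float(sig_r))
            st_all.append(float(sig_r + _hoop_minus_radial(mat, lam)))

    R_arr = np.array(R_all)
    r_arr = np.array(r_all)
    lam_th = r_arr / R_arr
    return TransmuralProfile(
        R_mm=R_arr,
        r_mm=r_arr,
        layer=np.array(lab_all),
        sigma_theta=np.array(st_all),
        sigma_r=np.array(sr_all),
        eps_theta=lam_th - 1.0,
        eps_r=np.abs(1.0 / lam_th - 1.0),
        pressure_mmHg=float(pressure_mmHg),
    )


# -- sweeps and compliance -------------------------------------------------


def pressure_sweep(
    vessel: VesselConfig,
    pressures_mmHg: Sequence[float],
    samples_per_layer: int = 16,
) -> pd.DataFrame:
    """Layer-mean strain curves over an ascending list of pressures.

    Returns one row per (pressure, layer) with the spatial mean of
    ``eps_theta`` and ``eps_r`` plus the deformed luminal radius.
    """
    p = list(pressures_mmHg)
    if len(p) < 2:
        raise ValueError("need at least 2 pressures")
    if any(b <= a for a, b in zip(p, p[1:])):
        raise ValueError("pressures must be sorted ascending")
    rows = []
    for pm in p:
        res = inflate(vessel, pm, samples_per_layer=samples_per_layer)
        stats = res.profile.layer_stats()
        for _, s in stats.iterrows():
            rows.append(
                {
                    "pressure_mmHg": pm,
                    "layer": s["layer"],
                    "eps_theta_mean": s["eps_theta_mean"],
                    "eps_r_mean": s["eps_r_mean"],
                    "luminal_radius_mm": res.luminal_radius_deformed_mm,
                }
            )
    return pd.DataFrame(rows)


def compliance(vessel: VesselConfig, p_dia_mmHg: float = 80.0, p_sys_mmHg: float = 120.0) -> float:
    """Relative luminal cross-sectional area change between two pressures.

    ``(A_sys - A_dia) / A_dia`` with ``A = pi r_i^2``; returned as a
    dimensionless fraction (multiply by 100 for percent).
    """
    if not (p_sys_mmHg > p_dia_mmHg >= 0):
        raise ValueError("need p_sys > p_dia >= 0")
    r_dia = inflate(vessel, p_dia_mmHg, samples_per_layer=2).luminal_radius_deformed_mm
    r_sys = inflate(vessel, p_sys_mmHg, samples_per_layer=2).luminal_radius_deformed_mm
    return (r_sys**2 - r_dia**2) / r_dia**2
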