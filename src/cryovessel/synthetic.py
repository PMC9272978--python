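"""Synthetic uniaxial compression data and fixture vessel builders.

No raw cryogel test records are publicly deposited, so the generator emits
curves with the statistical structure of the compression experiments: per
sample, constitutive coefficients are drawn from truncated normal
populations centred on the published per-composition means and SDs, the
"J"-shaped 10th-cycle stress magnitude is evaluated on a 0-50 % strain grid
through the constitutive module, and load-cell-like noise (multiplicative
plus additive Gaussian) is applied.  Everything is reproducible from the
seed.

The vessel builders assemble the three-layer artery (literature layer
coefficients) and graft (cryogel mean parameters per layup) configurations
with the reference thicknesses and the soft-tissue embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import truncnorm

from . import fixtures as fx
from .calibration import TestCurve
from .constitutive import nominal_stress, ogden, yeoh
from .inflation import Layer, VesselConfig, elastic_foundation

__all__ = [
    "GeneratorSpec",
    "generate_compression_curves",
    "curve_to_force_displacement",
    "graft_layup",
    "artery_model",
]

#: cast cylindrical sample geometry: 20 mm height x 10 mm diameter
SAMPLE_HEIGHT_MM = 20.0
SAMPLE_DIAMETER_MM = 10.0
SAMPLE_AREA_MM2 = np.pi * SAMPLE_DIAMETER_MM**2 / 4.0

#: lower truncation bounds on drawn coefficients
_TRUNC = {"mu1": 0.0, "alpha1": 2.0, "c10": 0.0}


@dataclass(frozen=True)
class GeneratorSpec:
    """Population and noise model for one composition's synthetic tests.

    Defaults reproduce the experimental conditions: 8 samples per
    composition, strain to 0.5 on 1000 points, coefficient means/SDs from
    the published per-composition tables, 1 % multiplicative plus 0.0005 MPa
    additive Gaussian noise approximating load-cell resolution.
    """

    composition: str = "P9G1-A-C"
    family: str = "ogden"
    means: Mapping[str, float] = field(default_factory=dict)
    sds: Mapping[str, float] = field(default_factory=dict)
    n_samples: int = 8
    max_strain: float = 0.5
    n_points: int = 1000
    multiplicative_sd: float = 0.01
    additive_sd_MPa: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("ogden", "yeoh"):
            raise ValueError("generating family must be ogden or yeoh")
        if self.composition not in fx.COMPOSITIONS and not self.means:
            raise ValueError(f"unknown composition {self.composition!r}")
        table = fx.CRYOGEL_OGDEN if self.family == "ogden" else fx.CRYOGEL_YEOH
        keys = ("mu1", "alpha1") if self.family == "ogden" else ("c10", "c20", "c30")
        means = dict(self.means) or {k: table[self.composition][k][0] for k in keys}
        sds = dict(self.sds) or {k: table[self.composition][k][1] for k in keys}
        if set(means) != set(keys) or set(sds) != set(keys):
            raise ValueError(f"means/sds must provide exactly {keys}")
        if any(s < 0 for s in sds.values()):
            raise ValueError("SDs must be nonnegative")
        for k, lo in _TRUNC.items():
            if k in means and means[k] + 5.0 * sds[k] <= lo:
                raise ValueError(f"truncation region empty for {k}")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)


def _draw(rng: np.random.Generator, mean: float, sd: float, lower: float | None) -> float:
    if sd == 0.0:
        return mean
    if lower is None:
        return float(rng.normal(mean, sd))
    a = (lower - mean) / sd
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def generate_compression_curves(spec: GeneratorSpec) -> list[TestCurve]:
    """Draw per-sample materials and emit noisy stress-strain magnitudes."""
    rng = np.random.default_rng(spec.seed)
    strain = np.linspace(0.0, spec.max_strain, spec.n_points)
    lam = 1.0 - strain
    curves = []
    for k in range(spec.n_samples):
        params = {
            key: _draw(rng, spec.means[key], spec.sds[key], _TRUNC.get(key))
            for key in spec.means
        }
        if spec.family == "ogden":
            mat = ogden([params["mu1"]], [params["alpha1"]])
        else:
            mat = yeoh(params["c10"], params["c20"], params["c30"])
        stress = np.abs(nominal_stress(mat, "uniaxial", lam))
        if spec.multiplicative_sd > 0:
            stress = stress * (1.0 + spec.multiplicative_sd * rng.standard_normal(stress.size))
        if spec.additive_sd_MPa > 0:
            stress = stress + spec.additive_sd_MPa * rng.standard_normal(stress.size)
        stress = np.clip(stress, 0.0, None)
        stress[0] = 0.0  # anchor the reference state
        curves.append(
            TestCurve(
                strain,
                stress,
                sample_id=f"{spec.composition}-s{k + 1}",
                composition=spec.composition,
                area_mm2=SAMPLE_AREA_MM2,
                initial_height_mm=SAMPLE_HEIGHT_MM,
            )
        )
    return curves


def curve_to_force_displacement(curve: TestCurve) -> tuple[np.ndarray, np.ndarray]:
    """Raw-dialect view of a curve: force (N) and displacement (mm).

    Uses the curve's own sample geometry (falling back to the cast-mold
    20 mm x 10 mm cylinder) so that the stress-strain conversion can be
    exercised end to end.
    """
    A = curve.area_mm2 or SAMPLE_AREA_MM2
    L0 = curve.initial_height_mm or SAMPLE_HEIGHT_MM
    return curve.stress * A, curve.strain * L0


# -- fixture vessels -------------------------------------------------------


def _three_layers(materials) -> tuple[Layer, ...]:
    return tuple(
        Layer(t, m, lab)
        for t, m, lab in zip(fx.LAYER_THICKNESSES_MM, materials, ("intima", "media", "adventitia"))
    )


def _default_bc() -> "elastic_foundation":
    return elastic_foundation(E_MPa=fx.SOFT_TISSUE["E_MPa"], nu=fx.SOFT_TISSUE["nu"])


def graft_layup(name: str, model_family: str = "ogden", luminal_radius_mm: float = 1.5) -> VesselConfig:
    """Three-layer graft vessel for one layup (PG-1..PG-4) and model family."""
    if name not in fx.GRAFT_LAYUPS:
        raise KeyError(f"unknown graft layup {name!r}; choose from {sorted(fx.GRAFT_LAYUPS)}")
    comp = fx.GRAFT_LAYUPS[name]
    mats = [fx.cryogel_material(comp[lab], model_family) for lab in ("intima", "media", "adventitia")]
    return VesselConfig(
        luminal_radius_mm=luminal_radius_mm,
        layers=_three_layers(mats),
        external_bc=_default_bc(),
        name=f"{name}-{model_family}",
    )


def artery_model(name: str, luminal_radius_mm: float = 1.5) -> VesselConfig:
    """Three-layer coronary artery vessel under one constitutive model."""
    if name not in fx.ARTERY_LAYERS:
        raise KeyError(f"unknown artery model {name!r}; choose from {sorted(fx.ARTERY_LAYERS)}")
    mats = [fx.artery_material(name, lab) for lab in ("intima", "media", "adventitia")]
    return VesselConfig(
        luminal_radius_mm=luminal_radius_mm,
        layers=_three_layers(mats),
        external_bc=_default_bc(),
        name=f"artery-{name}",
    )
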