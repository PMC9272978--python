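"""Published parameter sets shipped as read-only fixtures.

Three groups of constants:

* layer-specific coronary-artery hyperelastic coefficients from the
  literature (polynomial, reduced-polynomial and Ogden fits of the same
  layer-separated human coronary test data),
* per-composition mean +/- SD first-order Ogden and Yeoh coefficients of the
  four PVA/gelatin cryogel compositions, together with the derived initial
  shear moduli and measured densities,
* geometry and loading constants: wall-layer thicknesses, the soft-tissue
  embedding, and the pressure unit conversion.

Compositions are named ``P9G1-<A|B>-<C|NC>``: 9:1 PVA:gelatin by weight,
A/B the PVA molecular-weight grade (A = 146-186 kDa, B = 89-98 kDa) and
C/NC coagulation versus no coagulation post-treatment.
"""

from __future__ import annotations

import json
from importlib import resources

from .constitutive import HyperelasticMaterial, ogden, polynomial, reduced_polynomial, yeoh

__all__ = [
    "MMHG_TO_MPA",
    "LAYER_THICKNESSES_MM",
    "SOFT_TISSUE",
    "COMPOSITIONS",
    "CRYOGEL_OGDEN",
    "CRYOGEL_YEOH",
    "CRYOGEL_DENSITY",
    "ARTERY_LAYERS",
    "GRAFT_LAYUPS",
    "artery_material",
    "cryogel_material",
    "fixture_library",
]

#: pressure conversion, exact by convention
MMHG_TO_MPA = 133.322e-6

#: intima, media, adventitia reference thicknesses (mm)
LAYER_THICKNESSES_MM = (0.23, 0.30, 0.34)

#: Hookean surrounding connective tissue
SOFT_TISSUE = {"E_MPa": 0.05, "nu": 0.49}

DIASTOLIC_MMHG = 80.0
SYSTOLIC_MMHG = 120.0

COMPOSITIONS = ("P9G1-A-C", "P9G1-A-NC", "P9G1-B-C", "P9G1-B-NC")

# Per-composition first-order Ogden parameters, mean and SD over the n = 6
# included samples, plus the mean initial shear modulus and fit quality.
CRYOGEL_OGDEN = {
    "P9G1-A-C": {"mu1": (0.0444, 0.0060), "alpha1": (7.116, 0.528), "mu0": (0.157, 0.016), "r2": (0.9994, 0.0004)},
    "P9G1-A-NC": {"mu1": (0.0374, 0.0042), "alpha1": (6.553, 0.276), "mu0": (0.122, 0.012), "r2": (0.9988, 0.0008)},
    "P9G1-B-C": {"mu1": (0.0276, 0.0010), "alpha1": (7.765, 0.493), "mu0": (0.107, 0.009), "r2": (0.9994, 0.0003)},
    "P9G1-B-NC": {"mu1": (0.0227, 0.0025), "alpha1": (7.311, 0.581), "mu0": (0.083, 0.011), "r2": (0.9988, 0.0008)},
}

CRYOGEL_YEOH = {
    "P9G1-A-C": {"c10": (0.0205, 0.0035), "c20": (0.0015, 0.0028), "c30": (0.0042, 0.0017), "mu0": (0.0410, 0.0070), "r2": (0.9994, 0.0008)},
    "P9G1-A-NC": {"c10": (0.0180, 0.0024), "c20": (-0.0015, 0.0019), "c30": (0.0044, 0.0012), "mu0": (0.0360, 0.0049), "r2": (0.9984, 0.0009)},
    "P9G1-B-C": {"c10": (0.0126, 0.0006), "c20": (0.0015, 0.0014), "c30": (0.0032, 0.0006), "mu0": (0.0252, 0.0012), "r2": (0.9997, 0.0002)},
    "P9G1-B-NC": {"c10": (0.0108, 0.0014), "c20": (-0.0007, 0.0007), "c30": (0.0033, 0.0009), "mu0": (0.0217, 0.0027), "r2": (0.9985, 0.0007)},
}

#: measured densities, kg m^-3, mean and SD
CRYOGEL_DENSITY = {
    "P9G1-A-C": (1080.0, 36.0),
    "P9G1-A-NC": (1190.0, 19.0),
    "P9G1-B-C": (1070.0, 37.0),
    "P9G1-B-NC": (1120.0, 38.0),
}

# Literature coronary-artery layer coefficients (MPa; Ogden D1 in 1/MPa is
# retained on the card but unused by the incompressible evaluation path).
ARTERY_LAYERS = {
    "polynomial": {
        "intima": {"c10": -0.204, "c01": 0.223, "c20": 1.37, "c11": -3.71, "c02": 2.67},
        "media": {"c10": -0.117, "c01": 0.128, "c20": 0.224, "c11": -0.672, "c02": 0.569},
        "adventitia": {"c10": -0.189, "c01": 0.202, "c20": 0.459, "c11": -1.38, "c02": 1.34},
    },
    "reduced_polynomial": {
        "intima": {"c": [6.79e-3, 0.54, -1.11, 10.65, -7.27, 1.63]},
        "media": {"c": [6.52e-3, 4.89e-2, 9.26e-3, 0.76, -0.43, 8.69e-2]},
        "adventitia": {"c": [8.27e-3, 1.20e-2, 0.52, -5.63, 21.44, 0.00]},
    },
    "ogden": {
        "intima": {"mu": [-5.70, 3.58, 2.17], "alpha": [24.43, 25.00, 23.24], "d1": 0.85},
        "media": {"mu": [-1.84, 1.12, 0.73], "alpha": [21.71, 22.00, 21.20], "d1": 4.11},
        "adventitia": {"mu": [-1.99, 1.20, 0.81], "alpha": [24.61, 25.00, 23.90], "d1": 3.92},
    },
}

# Graft layups: intima fixed to the stiffest composition, media to the most
# compliant; the adventitia mimic is varied across the four compositions.
GRAFT_LAYUPS = {
    "PG-1": {"intima": "P9G1-A-C", "media": "P9G1-B-NC", "adventitia": "P9G1-A-C"},
    "PG-2": {"intima": "P9G1-A-C", "media": "P9G1-B-NC", "adventitia": "P9G1-A-NC"},
    "PG-3": {"intima": "P9G1-A-C", "media": "P9G1-B-NC", "adventitia": "P9G1-B-C"},
    "PG-4": {"intima": "P9G1-A-C", "media": "P9G1-B-NC", "adventitia": "P9G1-B-NC"},
}


def artery_material(model: str, layer: str) -> HyperelasticMaterial:
    """Material for one artery wall layer under the given constitutive model."""
    try:
        p = ARTERY_LAYERS[model][layer]
    except KeyError:
        raise KeyError(f"unknown artery model/layer {model!r}/{layer!r}") from None
    label = f"artery-{model}-{layer}"
    if model == "polynomial":
        c = {(1, 0): p["c10"], (0, 1): p["c01"], (2, 0): p["c20"], (1, 1): p["c11"], (0, 2): p["c02"]}
        return polynomial(c, order=2, label=label)
    if model == "reduced_polynomial":
        return reduced_polynomial(p["c"], label=label)
    return ogden(p["mu"], p["alpha"], d=(p["d1"],), label=label)


def cryogel_material(composition: str, family: str = "ogden") -> HyperelasticMaterial:
    """Mean-parameter material for a cryogel composition (ogden or yeoh)."""
    label = f"{composition}-{family}"
    if family == "ogden":
        p = CRYOGEL_OGDEN[composition]
        return ogden([p["mu1"][0]], [p["alpha1"][0]], label=label)
    if family == "yeoh":
        p = CRYOGEL_YEOH[composition]
        return yeoh(p["c10"][0], p["c20"][0], p["c30"][0], label=label)
    raise KeyError(f"unknown cryogel model family {family!r}")


def fixture_library() -> dict:
    """All fixed constants as one JSON-serializable dictionary."""
    return {
        "pressure": {
            "mmHg_to_MPa": MMHG_TO_MPA,
            "diastolic_mmHg": DIASTOLIC_MMHG,
            "systolic_mmHg": SYSTOLIC_MMHG,
        },
        "layer_thicknesses_mm": list(LAYER_THICKNESSES_MM),
        "soft_tissue": dict(SOFT_TISSUE),
        "artery_layers": ARTERY_LAYERS,
        "cryogel_ogden": CRYOGEL_OGDEN,
        "cryogel_yeoh": CRYOGEL_YEOH,
        "cryogel_density_kg_m3": CRYOGEL_DENSITY,
        "graft_layups": GRAFT_LAYUPS,
        "compositions": list(COMPOSITIONS),
    }


def fixture_json() -> str:
    """Canonical serialization used for the golden-file integrity check."""
    return json.dumps(fixture_library(), sort_keys=True, indent=1)


def golden_fixture_json() -> str:
    """Contents of the golden fixture file shipped with the package."""
    return resources.files("cryovessel").joinpath("data/fixtures_golden.json").read_text()
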