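import numpy as np
import pytest

from cryovessel import fixtures as fx
from cryovessel.calibration import TestCurve
from cryovessel.constitutive import neo_hookean, nominal_stress, ogden


@pytest.fixture(scope="session")
def nh_half():
    """Neo-Hookean with C10 = 0.5 MPa (mu0 = 1 MPa)."""
    return neo_hookean(0.5)


@pytest.fixture(scope="session")
def ogden_ac():
    """Mean first-order Ogden parameters of the stiffest cryogel composition."""
    return ogden([0.0444], [7.116], label="P9G1-A-C")


@pytest.fixture(scope="session")
def artery_materials():
    return {
        (model, layer): fx.artery_material(model, layer)
        for model in fx.ARTERY_LAYERS
        for layer in ("intima", "media", "adventitia")
    }


def make_ogden_curve(mu1=0.0444, alpha1=7.116, n=1000, max_strain=0.5, composition="P9G1-A-C"):
    """Noiseless compression-curve magnitudes from a first-order Ogden model."""
    strain = np.linspace(0.0, max_strain, n)
    lam = 1.0 - strain
    stress = np.abs(nominal_stress(ogden([mu1], [alpha1]), "uniaxial", lam))
    return TestCurve(strain, stress, sample_id="synthetic", composition=composition)


@pytest.fixture(scope="session")
def noiseless_ac_curve():
    return make_ogden_curve()
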