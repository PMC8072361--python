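import numpy as np
import pytest

from mbfdecon import (AIFParams, KineticParams, PhantomSpec, build_phantom,
                      generate_tissue_curve, synthesize_aif)


@pytest.fixture(scope="session")
def aif_params():
    return AIFParams()


@pytest.fixture(scope="session")
def aif(aif_params):
    """Default dual-Gaussian arterial input on the 0.7 s / 60 s grid."""
    return synthesize_aif(aif_params, duration=60.0, dt=0.7)


@pytest.fixture(scope="session")
def midrange_kinetics():
    """A mid-grid tile: Fp = 2.0 ml/min/g, Vp = 0.07 ml/g."""
    return KineticParams(Fp=2.0, Vp=0.07)


@pytest.fixture(scope="session")
def tissue(aif, midrange_kinetics):
    """Noiseless mid-grid tissue curve, zero delay."""
    return generate_tissue_curve(aif, midrange_kinetics)


@pytest.fixture(scope="session")
def small_phantom():
    """A 3x3 tile phantom with 4 realizations (fast, seeded)."""
    spec = PhantomSpec(fp_values=np.linspace(0.48, 3.9, 3),
                       vp_values=np.linspace(0.04, 0.1, 3),
                       realizations_per_tile=4, seed=7)
    return build_phantom(spec)
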