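import numpy as np
import pytest

from ctldyn.params import TumorImmuneParams, reference_parameters
from ctldyn.synthetic import NoiseModel, generate_full_dataset


@pytest.fixture(scope="session")
def ref_params() -> TumorImmuneParams:
    """Best-fit full-model reference estimate (HAVCR2-dominant)."""
    return reference_parameters("all")


@pytest.fixture(scope="session")
def mild_params() -> TumorImmuneParams:
    """A parameter set with smooth, non-collapsing dynamics.

    Used for generic simulator properties where the reference estimate's
    tumor-eradication course would obscure the property under test.
    """
    return TumorImmuneParams(
        s0=0.001, se=2.0, dE=0.5, di=2.0, kgs=1.64, ksg=0.66, ki=4.0,
        ke=2.0, kl=0.2, kt=0.8, kp=0.05, dl=0.5, dt=0.1, dp=2.0, dpl=2.0)


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Noise-free synthetic study generated from the reference estimate."""
    return generate_full_dataset(seed=1, noise=NoiseModel.none())


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default-noise synthetic study."""
    return generate_full_dataset(seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
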