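import numpy as np
import pytest

from fgmwalk import ModelSpec, preset_model


@pytest.fixture(scope="session")
def fig1_model():
    """Isotropic slow-change reference scenario (n=2, sigma^2=10, m^2=1,
    v1=1e-5, Theta=1; scaled rate of change 1e-4)."""
    return preset_model("fig1")


@pytest.fixture(scope="session")
def antagonistic_model():
    """Strong antagonistic correlations: rho_Sigma=0.9, rho_M=-0.9."""
    return ModelSpec.from_params(2, sigma_sq=10.0, rho_sigma=0.9, m_sq=1.0,
                                 rho_m=-0.9, v1=1e-5)


def random_pd_matrix(rng, n, scale=1.0):
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T + n * np.eye(n))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
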