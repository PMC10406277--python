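import numpy as np
import pytest

from blfdr import LinkStatsTable, ModelParams, gamma_shape, prior_prob_alt
from blfdr.mixture import HyperParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def hyper():
    return HyperParams()


@pytest.fixture
def table5():
    """Five-link fixture with three statistics above the alternative support."""
    t_f = np.array([0.3, 1.0, 1.5, 2.5, 0.9])
    t_s = np.array([0.5, 2.0, 0.1, 3.0, 1.0])
    return LinkStatsTable(t_f, t_s)


@pytest.fixture
def table1_params():
    """A parameter point near the posterior medians reported for the LLD fit."""
    return ModelParams(
        alpha=(1.120, -0.018), gamma=(-2.313, -0.692), beta=2.214, sigma0_sq=1.100
    )


def simulate_from_model(
    params: ModelParams,
    m: int,
    rng: np.random.Generator,
    mu1: float = 0.674,
    t_s_scale: float = 1.2,
) -> LinkStatsTable:
    """Draw a link-statistics table exactly from the mixture model.

    SC statistics are folded-normal draws; membership follows the logistic
    prior; null FC statistics are folded normal, alternative ones are
    mu1 + Gamma(shape(t_s), beta).
    """
    t_s = np.abs(rng.normal(0.0, t_s_scale, m))
    w = rng.random(m) < prior_prob_alt(t_s, params.gamma)
    t_f = np.abs(rng.normal(0.0, np.sqrt(params.sigma0_sq), m))
    if w.any():
        t_f[w] = mu1 + rng.gamma(gamma_shape(t_s[w], params.alpha), 1.0 / params.beta)
    return LinkStatsTable(t_f, t_s)


@pytest.fixture
def model_table(table1_params, rng):
    return simulate_from_model(table1_params, 3000, rng)
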