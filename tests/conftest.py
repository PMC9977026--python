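import numpy as np
import pytest

from itsmeta import (
    McmcConfig,
    SimulationConfig,
    build_design,
    center_scores,
    fit_model,
    generate_study,
)

DOMAIN = "reading"


@pytest.fixture(scope="session")
def default_config():
    """Default 69-school study restricted to one domain for speed."""
    return SimulationConfig(seed=11, domains=(DOMAIN,))


@pytest.fixture(scope="session")
def study(default_config):
    return generate_study(default_config)


@pytest.fixture(scope="session")
def centred_study(study):
    obs, profiles, reference, truth = study
    return center_scores(obs, reference), profiles, reference, truth


@pytest.fixture(scope="session")
def default_design(centred_study):
    centred, profiles, _, truth = centred_study
    return build_design(centred, profiles, DOMAIN, truth.event_year)


@pytest.fixture(scope="session")
def default_fit(default_design):
    """One shared MCMC fit of the default study (2 chains x 1000 iters)."""
    return fit_model(default_design, mcmc=McmcConfig(chains=2, iterations=1000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
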