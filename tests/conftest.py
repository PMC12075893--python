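import numpy as np
import pytest

from baskex import ExnexConfig, MCMCSettings, TrialStructure, make_fixture


@pytest.fixture(scope="session")
def config() -> ExnexConfig:
    """Default priors: q0=0.2, q1=0.4, pi=0.5, rho=0.3, diffuse normals."""
    return ExnexConfig()


@pytest.fixture(scope="session")
def tiny():
    """Small 2+1 trial (n=(8,8,6)) for fast end-to-end tests."""
    cfg, scenarios = make_fixture("tiny")
    return cfg, scenarios


@pytest.fixture(scope="session")
def tiny_structure() -> TrialStructure:
    return TrialStructure(n_existing=[8, 8], n_new=[6])


@pytest.fixture(scope="session")
def fast_mcmc() -> MCMCSettings:
    """Short chains for structural (non-numerical) assertions."""
    return MCMCSettings(n_chains=2, n_warmup=300, n_samples=600, seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2025)
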