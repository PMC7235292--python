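import numpy as np
import pytest

from ctxlearn import AgentParams, TaskConfig, simulate_session


@pytest.fixture(scope="session")
def default_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def agent() -> AgentParams:
    return AgentParams(alpha=0.3, kappa=-3.0)


@pytest.fixture(scope="session")
def session60(default_config, agent):
    """One default 60-trial session with stored ground-truth latents."""
    return simulate_session(default_config, agent, seed=1234)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
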