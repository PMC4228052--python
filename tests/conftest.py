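import numpy as np
import pytest

from margutil import AgentParams, GroundTruthUtility
from margutil.fractile import fit_utility
from margutil.pipeline import ExperimentConfig, measure_utility_sessions


@pytest.fixture(scope="session")
def truth() -> GroundTruthUtility:
    """Default s-shaped (convex-then-concave) ground-truth utility."""
    return GroundTruthUtility()


@pytest.fixture(scope="session")
def linear_truth() -> GroundTruthUtility:
    """Beta(1,1) CDF: the identity on the normalized domain."""
    return GroundTruthUtility(1.0, 1.0)


@pytest.fixture(scope="session")
def agent(truth) -> AgentParams:
    return AgentParams(utility=truth)


@pytest.fixture(scope="session")
def crisp_agent(agent) -> AgentParams:
    """High-sensitivity, lapse-free agent for parameter-recovery checks."""
    return agent.with_high_sensitivity()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


# -- expensive shared measurements (built once per test session) -----------

@pytest.fixture(scope="session")
def utility_sessions(crisp_agent):
    """14 fractile sessions at 3 repeats/node with the crisp agent."""
    cfg = ExperimentConfig()
    points, fits = measure_utility_sessions(
        crisp_agent, cfg, np.random.default_rng(2024))
    return points, fits


@pytest.fixture(scope="session")
def consensus_fit(utility_sessions, truth):
    points, _ = utility_sessions
    return fit_utility(points, domain=truth.domain)


@pytest.fixture(scope="session")
def noisy_consensus_fit(agent, truth):
    """Pooled-session fit measured with the default (noisy) agent."""
    cfg = ExperimentConfig()
    points, _ = measure_utility_sessions(
        agent, cfg, np.random.default_rng(2024), fit_each=False)
    return fit_utility(points, domain=truth.domain)


@pytest.fixture(scope="session")
def linear_points(linear_truth):
    """Pooled fractile points measured on a linear-truth agent."""
    agent_lin = AgentParams(utility=linear_truth)
    cfg = ExperimentConfig()
    points, _ = measure_utility_sessions(
        agent_lin, cfg, np.random.default_rng(2024), fit_each=False)
    return points


@pytest.fixture(scope="session")
def linear_consensus_fit(linear_points, linear_truth):
    return fit_utility(linear_points, domain=linear_truth.domain)
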