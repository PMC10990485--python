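import numpy as np
import pytest

from rotgen.models import PredictionContext
from rotgen.simulate import AgentSpec, simulate_participant
from rotgen.task import build_schedule


@pytest.fixture(scope="session")
def ctx_canonical():
    """Training distribution of Exp. 1 (canonical rotation only)."""
    return PredictionContext((0,))


@pytest.fixture(scope="session")
def ctx_mixed():
    """Training distribution of Exp. 2-4 (canonical + 90 degrees)."""
    return PredictionContext((0, 90))


@pytest.fixture(scope="session")
def exp1a_schedule():
    return build_schedule("1a", 123)


@pytest.fixture(scope="session")
def agent_datasets(exp1a_schedule):
    """A small bank of seeded agents over the Exp. 1a schedule."""
    def make(model, beta, seed, schedule=exp1a_schedule):
        return simulate_participant(AgentSpec(model, beta, seed), schedule)

    return {
        "2D_clean": make("2D", 0.001, 42),
        "2D_noisy": make("2D", 0.2, 43),
        "R": make("R", 0.2, 44),
        "Rp": make("Rp", 0.05, 45),
        "1Di_u": make("1Di_u", 0.05, 46),
        "1Di_u_clean": make("1Di_u", 0.001, 47),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
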