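import numpy as np
import pytest

from moralcog import synthetic
from moralcog.types import DeciderParams, InferenceParams, PredictionRecord
from moralcog.decision import choice_prob, harm_utility


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def default_params():
    return DeciderParams(kappa_self=0.45, kappa_other=0.6, beta=5.0)


@pytest.fixture
def trials(rng):
    return synthetic.generate_decision_trials(60, seed=rng)


def make_session(agent_label: str, n_trials: int = 60, seed: int = 0):
    """Observed agent choices for one inference session (no predictions)."""
    rng = np.random.default_rng(seed)
    agent = synthetic.make_agent(agent_label)
    trials = synthetic.generate_decision_trials(n_trials, seed=rng)
    session = []
    for t in trials:
        p = choice_prob(harm_utility(t.dm, t.ds, agent.kappa_o), agent.beta_agent)
        session.append(
            PredictionRecord(trial=t, agent_choice=bool(rng.random() < p))
        )
    return agent, session


@pytest.fixture
def benchmark_session():
    """The default 60-trial session used for oracle-agreement checks."""
    return make_session("good", 60, seed=0)
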