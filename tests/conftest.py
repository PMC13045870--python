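import numpy as np
import pytest

import openrig as org


@pytest.fixture(scope="session")
def two_choice_config():
    return org.load_config("two_choice")


@pytest.fixture(scope="session")
def gonogo_config():
    return org.load_config("gonogo")


@pytest.fixture(scope="session")
def expert_policy():
    """A well-trained, fully engaged virtual mouse."""
    return org.AgentPolicy(d_true=3.0, c_true=0.0, lapse=0.0, p_lick_decision=1.0)


@pytest.fixture(scope="session")
def small_session(two_choice_config, expert_policy):
    """A short simulated two-choice session shared across tests."""
    import copy

    cfg = copy.deepcopy(two_choice_config)
    cfg.max_rewards = 25
    return org.run_session(cfg, expert_policy, seed=11)


@pytest.fixture(scope="session")
def small_session_record(small_session):
    session, excluded = org.build_session(small_session)
    assert excluded == []
    return session


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
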