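import numpy as np
import pytest

import costdiscount as cd


@pytest.fixture(scope="session")
def stimuli():
    """Shared discriminative stimulus set (2 blocks x 100 pairs)."""
    return cd.design_exp1_stimuli(seed=11)


@pytest.fixture(scope="session")
def sigmoidal_dataset(stimuli):
    """One simulated sigmoidal subject on the shared stimuli."""
    agent = cd.Agent("sigmoidal", {"k": 10.0, "p": 0.7}, beta=0.5, subject="sim01")
    return cd.simulate_cohort([agent], stimuli, seed=21)[0]


@pytest.fixture(scope="session")
def hyperbolic_dataset(stimuli):
    agent = cd.Agent("hyperbolic", {"k": 5.0}, beta=0.4, subject="sim02")
    return cd.simulate_cohort([agent], stimuli, seed=22)[0]


def make_agent(model="sigmoidal", k=10.0, p=0.7, beta=0.5, subject="agent"):
    params = {"k": k}
    if model in ("sigmoidal", "power"):
        params["p"] = p
    return cd.Agent(model=model, params=params, beta=beta, subject=subject)
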