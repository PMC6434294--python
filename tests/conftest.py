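import numpy as np
import pytest

import frechetbayes as fb


@pytest.fixture(scope="session")
def survival_data():
    return fb.head_neck_survival()


@pytest.fixture(scope="session")
def survival_ml(survival_data):
    return fb.fit_mle(survival_data)


@pytest.fixture(scope="session")
def sim_data_123():
    """A medium sample from the (1, 2, 3) reference configuration."""
    return fb.sample(fb.FrechetParams(1.0, 2.0, 3.0), 200, seed=20240917)


@pytest.fixture(scope="session")
def sim_fit_123(sim_data_123):
    ml = fb.fit_mle(sim_data_123)
    fisher = fb.observed_fisher(ml.params, sim_data_123)
    return ml, fisher


def random_params(rng):
    """A parameter triple drawn from a moderate, well-conditioned range."""
    return fb.FrechetParams(
        float(rng.uniform(0.5, 3.0)),
        float(rng.uniform(0.5, 4.0)),
        float(rng.uniform(-2.0, 4.0)),
    )
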