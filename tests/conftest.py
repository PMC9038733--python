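import numpy as np
import pytest

from crowdmix.models import Condition, Model, ModelParams, TrialRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def crowded_trial():
    return TrialRecord(observer="o1", condition=Condition.FA, target=40,
                       flankers=(70, 120, 70, 120), global_ori=15, response=42)


@pytest.fixture
def gl_params():
    return ModelParams(gamma=0.10, sigma=8.0, beta_loc=0.15, beta_glo=0.08)


def random_crowded_trial(rng, observer="o1", condition=Condition.FA):
    """A random valid crowded trial with a response."""
    a, b = rng.integers(1, 181, size=2)
    while b == a:
        b = rng.integers(1, 181)
    return TrialRecord(observer=observer, condition=condition,
                       target=int(rng.integers(1, 181)),
                       flankers=(int(a), int(b), int(a), int(b)),
                       global_ori=int(rng.integers(1, 181)),
                       response=float(rng.uniform(0, 180)))


def random_valid_params(rng, model=Model.GLOBAL_LOCAL):
    """Random valid mixture parameters for a given model."""
    w = rng.dirichlet(np.ones(4))
    sigma = float(rng.uniform(1.5, 45.0))
    if model is Model.STANDARD:
        return ModelParams(gamma=float(w[1]), sigma=sigma)
    if model is Model.LOCAL:
        return ModelParams(gamma=float(w[1]), sigma=sigma, beta_loc=float(w[2]))
    return ModelParams(gamma=float(w[1]), sigma=sigma,
                       beta_loc=float(w[2]), beta_glo=float(w[3]))
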