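import numpy as np
import pytest

from painfilter import (
    FilterParams,
    StimulusSchedule,
    WorldParams,
    hierarchical_defaults,
    single_layer_defaults,
    split_streams,
)


@pytest.fixture
def single_params() -> FilterParams:
    return single_layer_defaults()


@pytest.fixture
def hier_params() -> FilterParams:
    return hierarchical_defaults()


@pytest.fixture
def world() -> WorldParams:
    return WorldParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_schedule(seed: int, n_steps: int, m: int = 1) -> StimulusSchedule:
    """A rough schedule with varying inputs and noise levels, for property
    tests that should hold irrespective of the protocol."""
    g = np.random.default_rng(seed)
    u = np.where(g.uniform(size=(n_steps, m)) < 0.2, g.uniform(0, 3.7, (n_steps, m)), 0.0)
    u_tilde = np.where(g.uniform(size=n_steps) < 0.2, g.uniform(0, 3.7, n_steps), 0.0)
    R = g.choice([0.8**2, 1.8**2, 8.0**2, 800.0**2], size=n_steps)
    return StimulusSchedule(u_tilde=u_tilde, u=u, R=R)
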