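import numpy as np
import pytest

import gradientspace as gs


@pytest.fixture(scope="session")
def scheme400():
    return gs.default_scheme()


@pytest.fixture(scope="session")
def scheme_small():
    return gs.small_scheme(70)


@pytest.fixture(scope="session")
def template_small(scheme_small):
    return gs.make_template(scheme_small, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_timeseries(scheme_small):
    """A short noisy scan drawn from the generative model."""
    tpl = gs.make_template(scheme_small, seed=3)
    ts, motion, _ = gs.simulate_subject(tpl, None, T=120, seed=11, spike_rate_per_minute=1.0)
    return ts, motion
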