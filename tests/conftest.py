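import numpy as np
import pytest

import tamrisk as tr


@pytest.fixture(scope="session")
def paper_config():
    return tr.default_config()


@pytest.fixture(scope="session")
def paper_model(paper_config):
    """Default six-effect generating model, baseline calibrated to ~112/401 events."""
    return tr.calibrate_baseline(tr.default_generating_model(), paper_config)


@pytest.fixture(scope="session")
def paper_cohort(paper_config, paper_model):
    return tr.generate_cohort(paper_config, paper_model, seed=20_001)


def make_survival(n, rng, lp=None, base=0.1, cens=0.1, admin=12.0):
    """Small exponential proportional-hazards draw used across tests."""
    lp = np.zeros(n) if lp is None else lp
    t_ev = rng.exponential(1.0 / (base * np.exp(lp - lp.mean())))
    t_c = np.minimum(rng.exponential(1.0 / cens, n), admin)
    return np.minimum(t_ev, t_c), (t_ev <= t_c).astype(int)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
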