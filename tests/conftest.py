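import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emgonset as eo

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_subject():
    """Two short synthetic sessions (6 trials each) with ground truth."""
    cfg = eo.SynthConfig(n_trials=6, n_sessions=2, seed=11)
    pairs = eo.simulate_subject(cfg)
    recs = [p[0].preprocessed() for p in pairs]
    gts = [p[1] for p in pairs]
    return cfg, recs, gts


@pytest.fixture(scope="session")
def small_session(small_subject):
    cfg, recs, gts = small_subject
    return recs[0], gts[0]


@pytest.fixture(scope="session")
def small_features(small_session):
    rec, _ = small_session
    return eo.feature_matrix(rec, names=eo.OPERATING_SET)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
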