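import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import isogamm as ig

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """One reduced synthetic study (8 athletes, 2-deg grid) plus its truth."""
    cfg = ig.GeneratorConfig(n_athletes=8, angle_step_deg=2.0, seed=42)
    df, truth = ig.simulate_dataset(cfg)
    return df, truth


@pytest.fixture(scope="session")
def small_fit(small_study):
    """A quick single-chain fit of the concentric-extension dataset."""
    df, _ = small_study
    groups = ig.preprocess(df)
    series = groups[("extension", "concentric")]
    return ig.fit_hgam(series, n_iter=500, n_warmup=200, seed=7, n_chains=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
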