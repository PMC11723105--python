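import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from droughtscreen import pipeline, synthetic

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_panel() -> pd.DataFrame:
    """Default synthetic 14×2×3 panel, seed 0."""
    return synthetic.simulate_trait_panel(synthetic.default_design(seed=0))


@pytest.fixture(scope="session")
def default_effects() -> synthetic.EffectSpec:
    return synthetic.default_effects(synthetic.default_design(seed=0))


@pytest.fixture(scope="session")
def drought_means(default_panel) -> pd.DataFrame:
    return pipeline.trait_means(default_panel, "drought")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def single_trait_effects(sigma_g=1.0, sigma_ge=0.5, sigma_eps=1.0,
                         sigma_b=0.5, mu=50.0, beta=-5.0) -> synthetic.EffectSpec:
    """One-trait effect spec with uniform cluster shift (helper for
    variance-component tests)."""
    te = pd.DataFrame(
        {"mu": [mu], "beta": [beta], "sigma_g": [sigma_g],
         "sigma_ge": [sigma_ge], "sigma_eps": [sigma_eps], "sigma_b": [sigma_b]},
        index=pd.Index(["T"], name="trait"))
    return synthetic.EffectSpec(te)
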