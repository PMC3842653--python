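import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded sub-region dataset shared across tests."""
    from firegam.synth import SyntheticConfig, simulate_dataset

    return simulate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def subregion_spec():
    from firegam.gam import ModelSpec, SmoothTerm, TensorTerm

    return ModelSpec(
        linear_terms=("fire_pm", "prop_income_gt50k", "prop_age_lt24"),
        indicator_terms=("is_monday", "is_tuesday", "is_sr3", "is_sr6"),
        smooth_terms=(SmoothTerm("anthro_pm25", 10),),
        tensor_terms=(TensorTerm("mean_rh", "min_temp", 5, 5),),
    )


@pytest.fixture(scope="session")
def subregion_fit(default_dataset, subregion_spec):
    from firegam.gam import fit_binomial_gam

    return fit_binomial_gam(subregion_spec, default_dataset["model_frame"])


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def small_glm_frame(rng):
    """Small smooth-free binomial dataset for GLM-level checks."""
    n = 120
    x = rng.normal(size=n)
    ind = (rng.random(n) < 0.5).astype(float)
    trials = np.full(n, 400.0)
    eta = -2.0 + 0.4 * x + 0.3 * ind
    y = rng.binomial(400, 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame({"visits": y, "population": trials, "x": x, "ind": ind})
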