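import numpy as np
import pandas as pd
import pytest
from scipy import special

from larvastat import BehaviorSimConfig, MeaSimConfig, ModelSpec, SmoothTerm, simulate_bins


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def gamm_spec():
    return ModelSpec(
        response="value",
        fixed_factors=("treatment", "phase"),
        interactions=(("treatment", "phase"),),
        smooth_terms=(SmoothTerm("time_s"),),
        random_intercept_factor="animal",
        family="beta-logit",
    )


@pytest.fixture(scope="session")
def vsr_spec():
    return ModelSpec(
        response="vsr_cm",
        fixed_factors=("treatment", "startle_phase"),
        interactions=(),
        smooth_terms=(),
        random_intercept_factor="animal",
        family="gaussian-identity",
    )


@pytest.fixture(scope="session")
def small_bins():
    """Small simulated bin table with the default dark-phase effect."""
    cfg = BehaviorSimConfig(n_per_group=8, seed=11)
    table, truth = simulate_bins(cfg)
    return table, truth


def make_beta_data(
    n_groups=10,
    obs_per_group=6,
    intercept=0.0,
    phi=20.0,
    sigma_b=0.0,
    seed=0,
    treatment_effect=0.0,
):
    """Beta responses from an intercept(+treatment) model with random intercepts."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        trt = "B" if (treatment_effect and g >= n_groups // 2) else "A"
        b = rng.normal(0, sigma_b) if sigma_b > 0 else 0.0
        for j in range(obs_per_group):
            eta = intercept + (treatment_effect if trt == "B" else 0.0) + b
            mu = special.expit(eta)
            y = float(np.clip(rng.beta(mu * phi, (1 - mu) * phi), 1e-9, 1 - 1e-9))
            rows.append((f"g{g}", trt, float(j), y))
    return pd.DataFrame(rows, columns=["animal", "treatment", "time_s", "value"])
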