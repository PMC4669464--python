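import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import vcmm as V


@pytest.fixture(scope="session")
def rate_params():
    return V.RateParameters(michaelis_constant=2.0)


@pytest.fixture(scope="session")
def tf_params():
    """Analytical parameters matching the gene-regulation fixture."""
    return V.TFModelParams.from_sim_spec(V.fixture("fig1b_like"))


@pytest.fixture(scope="session")
def genereg_nobind():
    """Expression-only version of the gene-regulation fixture."""
    import dataclasses

    return dataclasses.replace(
        V.fixture("fig1b_like"),
        binding_model="none",
        ns_binding=(0.0, 0.0),
        sp_binding=(0.0, 0.0),
    )


def random_distribution(rng, k_max=6, scale=10.0):
    """A random nonnegative discrete concentration distribution."""
    k = int(rng.integers(1, k_max + 1))
    support = np.sort(rng.uniform(0.0, scale, k)) + np.arange(k) * 1e-3
    weights = rng.integers(1, 50, k).astype(float)
    probs = weights / weights.sum()
    return V.DiscreteConcentrationDistribution(tuple(support), tuple(probs))
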