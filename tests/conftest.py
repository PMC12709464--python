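import numpy as np
import pandas as pd
import pytest

from unmask import (
    ColliderSimConfig,
    TrialDataset,
    TrialSchema,
    simulate_collider,
)


def make_discrete_dataset(n: int = 400, seed: int = 0) -> TrialDataset:
    """Fully discrete (binary X, A, E, Z) dataset for saturated-model checks."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, n)
    Z = rng.integers(0, 2, n)
    A = rng.integers(0, 2, n)
    E = rng.integers(0, 2, n)
    Y = rng.normal(size=n) + 2.0 * A + 1.5 * E + 0.5 * Z + 0.3 * X
    df = pd.DataFrame({"x": X, "A": A, "E": E, "z": Z, "Y": Y})
    schema = TrialSchema(
        treatment="A", expectancy="E", outcome="Y",
        covariates=("x",), post_confounders=("z",),
    )
    return TrialDataset(df, schema)


@pytest.fixture(scope="session")
def discrete_data() -> TrialDataset:
    return make_discrete_dataset()


@pytest.fixture(scope="session")
def collider_draw():
    """Moderate-size draw of the default collider world plus its oracle."""
    return simulate_collider(ColliderSimConfig(n=20_000, seed=11))


# Collider configuration with good overlap, used by robustness tests where
# extreme belief propensities would entangle clipping with the property
# being checked.
MILD_COLLIDER = dict(kappa_0=0.0, kappa_A=1.0, kappa_U=1.0,
                     beta_A=-10.0, beta_U=-12.0)
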