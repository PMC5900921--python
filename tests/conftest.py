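import numpy as np
import pandas as pd
import pytest

from domprof import (DimensionSpec, McmcSettings, ModelSpec, SyntheticConfig,
                     default_config, generate_population)


@pytest.fixture(scope="session")
def gauss2_config():
    """Balanced two-dimensional gaussian toy: J=10 providers, 20 patients
    each, no covariates."""
    dims = (DimensionSpec("a", "gaussian"), DimensionSpec("b", "gaussian"))
    return SyntheticConfig(
        J=10, n_j=20, dimensions=dims, alpha=np.array([1.0, 2.0]),
        beta={"a": np.array([]), "b": np.array([])}, covariate_model={},
        tau=np.array([0.5, 0.8]), rho_theta=np.array([[1, 0.5], [0.5, 1]]),
        sigma=np.array([1.0, 1.5]), rho_eps=np.array([[1, 0.3], [0.3, 1]]),
        seed=3,
    )


@pytest.fixture(scope="session")
def gauss2_data(gauss2_config):
    return generate_population(gauss2_config)


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-structured cohort for smoke tests (J=15, n_j=25)."""
    return generate_population(default_config(J=15, n_j=25, seed=7, missing=False))


@pytest.fixture
def short_settings():
    return McmcSettings(iterations=400, burn_in=150, seed=11)
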