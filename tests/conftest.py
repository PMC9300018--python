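import numpy as np
import pandas as pd
import pytest

from ecoira.ordination import BiomassMatrix, filter_species, run_pca
from ecoira.synthetic import simulate_dataset


def ar1_series(n, rho, rng, sd=1.0, mean=0.0):
    """Stationary AR(1) draw used as an independent noise oracle."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - rho**2)) if rho != 0 else rng.normal(0, sd)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + rng.normal(0.0, sd)
    return mean + x


@pytest.fixture(scope="session")
def default_dataset():
    """One default-parameter synthetic study, shared across tests."""
    return simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def default_pca(default_dataset):
    return run_pca(filter_species(default_dataset.biomass, 21), inclusion_threshold=21)


@pytest.fixture()
def small_matrix():
    """Tiny hand-checkable biomass matrix: 8 years x 5 species."""
    rng = np.random.default_rng(123)
    years = np.arange(2000, 2008)
    data = pd.DataFrame(
        np.exp(rng.normal(1.0, 0.8, size=(8, 5))),
        index=years, columns=[f"s{i}" for i in range(5)],
    )
    return BiomassMatrix(data, area="toy")
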