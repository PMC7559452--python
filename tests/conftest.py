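import numpy as np
import pandas as pd
import pytest

from smorfpred import SimulationConfig, simulate_expression, simulate_genome_and_platform
from smorfpred.pipeline import bundle_to_datasets


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_genes=120,
        n_smorfs=2,
        n_samples=24,
        n_datasets=2,
        n_gene_sets=6,
        gene_set_size=15,
    )


@pytest.fixture(scope="session")
def platform(small_config):
    return simulate_genome_and_platform(small_config)


@pytest.fixture(scope="session")
def expression(small_config):
    return simulate_expression(small_config)


@pytest.fixture(scope="session")
def datasets(platform, expression):
    return bundle_to_datasets(expression, platform.truth_annotations())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def random_expression(rng, n_features=40, n_samples=15, prefix="g", ties=False):
    values = rng.normal(7.0, 1.5, size=(n_features, n_samples))
    if ties:
        mask = rng.random(values.shape) < 0.3
        values[mask] = np.round(values[mask], 0)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i:04d}" for i in range(n_features)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )
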