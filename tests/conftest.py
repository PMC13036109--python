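import numpy as np
import pytest

from cytomod import (ModelConfig, SimulationConfig, build_graph, generate_cohort,
                     louvain_partition, stratified_split, train_model,
                     zscore_normalize)


@pytest.fixture(scope="session")
def toy_config():
    """Small, quick cohort: 120 genes in 6 modules, strong planted effects."""
    return SimulationConfig(
        n_genes=120, n_modules=6, n_deg_up=6, n_deg_down=6,
        n_ra=80, n_control=40, deg_allocation="graded", seed=7,
    )


@pytest.fixture(scope="session")
def toy_cohort(toy_config):
    return generate_cohort(toy_config)


@pytest.fixture(scope="session")
def toy_split(toy_cohort):
    return stratified_split(toy_cohort, train_fraction=0.7, seed=7)


@pytest.fixture(scope="session")
def toy_normalized(toy_split):
    train_z = zscore_normalize(toy_split.train)
    test_z = zscore_normalize(toy_split.test, reference=toy_split.train)
    return train_z, test_z


@pytest.fixture(scope="session")
def toy_graph(toy_normalized):
    train_z, _ = toy_normalized
    return build_graph(train_z, fraction=0.05, gamma=4.0)


@pytest.fixture(scope="session")
def toy_partition(toy_graph):
    return louvain_partition(toy_graph, seed=7)


@pytest.fixture(scope="session")
def toy_trained(toy_normalized, toy_graph, toy_partition):
    train_z, _ = toy_normalized
    config = ModelConfig(seed=7, max_epochs=30, early_stop_patience=8)
    return train_model(train_z, toy_graph, toy_partition, config)
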