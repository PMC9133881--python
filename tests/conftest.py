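import numpy as np
import pandas as pd
import pytest

from cernapipe.pipeline import run_pipeline_dataset
from cernapipe.simulate import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted-truth fixture (2000/100/50 features, seed 42)."""
    return simulate_dataset(SimulationParams())


@pytest.fixture(scope="session")
def default_result(default_dataset):
    return run_pipeline_dataset(default_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced fixture for fast pipeline-level tests."""
    params = SimulationParams(
        n_mrna=300, n_lnc=40, n_mir=16, n_triples=4, module_sizes=(35, 30), seed=7
    )
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    return run_pipeline_dataset(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def truth_module_labels(dataset, gene_index) -> pd.Series:
    labels = pd.Series(0, index=gene_index)
    for i, (_, mod) in enumerate(sorted(dataset.truth.modules.items()), start=1):
        labels[labels.index.intersection(mod["genes"])] = i
    return labels
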