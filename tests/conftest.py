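import numpy as np
import pandas as pd
import pytest

from omicstrata import synthetic_data as sd
from omicstrata.matrix import OmicsMatrix


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(
        n_samples=60,
        n_genes=300,
        n_subtypes=3,
        hazard_ratios=(1.0, 2.0, 4.0),
        block_effect=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return sd.generate_multiomics(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, kind="cnv_logratio", genes=None, samples=None) -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(kind, pd.DataFrame(values, index=genes, columns=samples))
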