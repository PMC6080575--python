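import numpy as np
import pandas as pd
import pytest

from devmeta.networks import MeasurementTable, Network
from devmeta.synthetic import generate_planted_networks


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_network(rng):
    w = rng.random((5, 5))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return Network(weights=w, node_names=[f"n{i}" for i in range(5)])


@pytest.fixture
def simple_table():
    values = pd.DataFrame(
        {
            "roiA": [1.0, 2.0, 3.0, 4.0],
            "roiB": [1.0, 3.0, 2.0, 4.0],
            "roiC": [4.0, 3.0, 2.0, 1.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    covariates = pd.DataFrame(
        {
            "gender": ["F", "F", "M", "M"],
            "score": [0.1, 0.4, 0.2, 0.3],
        },
        index=values.index,
    )
    return MeasurementTable(timepoint_label=7, values=values, covariates=covariates)


@pytest.fixture(scope="session")
def planted_default():
    """Default planted sequence shared by read-only tests."""
    return generate_planted_networks(seed=0)
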