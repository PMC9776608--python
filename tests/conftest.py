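import numpy as np
import pandas as pd
import pytest

from prostnet import NetworkModel, ar_nfkb_model


@pytest.fixture(scope="session")
def model() -> NetworkModel:
    return ar_nfkb_model()


@pytest.fixture()
def toy_de_table() -> pd.DataFrame:
    """Six genes spanning both directions and significance levels."""
    return pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3", "g4", "g5", "g6"],
            "log2fc": [2.0, -3.0, 4.0, 0.5, 2.0, 1.2],
            "pvalue": [0.001, 0.002, 0.1, 0.001, 0.4, 0.004],
            "adj_p": [0.01, 0.02, 0.2, 0.01, 0.5, 0.03],
        }
    )


def random_stable_model(rng: np.random.Generator, n: int = 4) -> NetworkModel:
    """A random diagonally dominant (hence stable) network."""
    A = rng.uniform(-0.5, 0.5, size=(n, n))
    np.fill_diagonal(A, 0.0)
    d = np.abs(A).sum(axis=1) + rng.uniform(0.5, 1.5, size=n)
    J = rng.uniform(0.1, 2.0, size=n)
    labels = [f"n{i}" for i in range(n)]
    return NetworkModel(labels=labels, J=J, d=d, A=A)
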