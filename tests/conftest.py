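"""Shared fixtures: small deterministic connectomes and model parameters."""

import numpy as np
import pandas as pd
import pytest

from connfit.connectome import Connectome
from connfit.params import DMFParams
from connfit.synthetic import generate_connectome


def region_table(n, n_subcortical=1):
    is_sub = np.zeros(n, dtype=bool)
    if n_subcortical:
        is_sub[-n_subcortical:] = True
    return pd.DataFrame(
        {
            "region_id": np.arange(n),
            "label": [f"r{i}" for i in range(n)],
            "hemisphere": ["left" if i % 2 == 0 else "right" for i in range(n)],
            "is_subcortical": is_sub,
        }
    )


def ring_connectome(n=6, weight=0.05, length=30.0):
    """Deterministic ring graph: each region couples to its two neighbours."""
    w = np.zeros((n, n))
    d = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n
        w[i, j] = w[j, i] = weight
        d[i, j] = d[j, i] = length
    return Connectome(weights=w, lengths=d, regions=region_table(n))


@pytest.fixture(scope="session")
def small_connectome():
    """A 12-region synthetic connectome shared across the suite."""
    return generate_connectome(12, density=0.4, seed=321)


@pytest.fixture(scope="session")
def ring6():
    return ring_connectome(6)


@pytest.fixture
def params():
    return DMFParams()
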