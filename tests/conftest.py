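import numpy as np
import pandas as pd
import pytest

from psychnet.data import CATEGORICAL, CONTINUOUS, CohortDataset, NetworkModel, VariableSpec


def make_continuous_dataset(arr, names=None, communities=None):
    """Wrap a numeric array as an all-continuous CohortDataset."""
    arr = np.asarray(arr, dtype=float)
    p = arr.shape[1]
    names = names or [f"V{i+1}" for i in range(p)]
    communities = communities or ["A"] * p
    specs = [VariableSpec(n, CONTINUOUS, community=c) for n, c in zip(names, communities)]
    return CohortDataset(pd.DataFrame(arr, columns=names), specs)


def random_network(rng, p=6, communities=None, density=0.5, signed=True):
    """Random symmetric weighted network for oracle comparisons."""
    nodes = [f"N{i+1}" for i in range(p)]
    communities = communities or {v: ("A" if i % 2 == 0 else "B") for i, v in enumerate(nodes)}
    w = np.zeros((p, p))
    sd = np.ones((p, p), dtype=bool)
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                mag = rng.uniform(0.05, 0.9)
                if signed and rng.random() < 0.4:
                    w[i, j] = w[j, i] = -mag
                else:
                    w[i, j] = w[j, i] = mag
                if rng.random() < 0.2:
                    # unsigned (categorical-style) edge: magnitude only
                    w[i, j] = w[j, i] = mag
                    sd[i, j] = sd[j, i] = False
    return NetworkModel(nodes=nodes, communities=communities, weights=w, sign_defined=sd)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mixed_dataset(rng):
    """Small mixed-type dataset: 3 continuous columns + 1 binary categorical."""
    n = 400
    x1 = rng.standard_normal(n)
    x2 = 0.5 * x1 + rng.standard_normal(n)
    x3 = rng.standard_normal(n)
    g = (x2 + rng.standard_normal(n) > 0).astype(float)
    values = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3, "g": g})
    specs = [
        VariableSpec("x1", CONTINUOUS, community="A"),
        VariableSpec("x2", CONTINUOUS, community="A"),
        VariableSpec("x3", CONTINUOUS, community="B"),
        VariableSpec("g", CATEGORICAL, levels=(0, 1), community="B"),
    ]
    return CohortDataset(values, specs)
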