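import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from spotlayer.model import CATEGORICAL, CONTINUOUS, SpotTable


def random_table(rng: np.random.Generator, n=None, with_diameter=None,
                 with_missing=True) -> SpotTable:
    """A random valid spot table with one categorical and one continuous
    annotation, optionally with missing values and a diameter."""
    n = int(rng.integers(1, 40)) if n is None else n
    table = SpotTable(
        ids=[f"s{i}" for i in range(n)],
        x=rng.uniform(-50, 50, n),
        y=rng.uniform(-50, 50, n),
    )
    if with_diameter is None:
        with_diameter = bool(rng.integers(2))
    if with_diameter:
        if rng.integers(2):
            table.diameter = float(rng.uniform(0.5, 3.0))
        else:
            table.diameter = rng.uniform(0.5, 3.0, n)
    labels = np.array(["alpha", "beta", "gamma"], dtype=object)
    cat = labels[rng.integers(0, 3, n)]
    cont = rng.normal(0, 10, n)
    if with_missing:
        cat[rng.random(n) < 0.1] = None
        cont[rng.random(n) < 0.1] = np.nan
    table = table.with_annotation("group", CATEGORICAL, cat)
    table = table.with_annotation("value", CONTINUOUS, cont)
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    table = SpotTable(ids=["s1", "s2", "s3"], x=[0.0, 1.0, 2.0],
                      y=[0.0, 0.5, 1.0], diameter=0.5)
    table = table.with_annotation("domain", CATEGORICAL, ["L1", "L2", "L1"])
    table = table.with_annotation("expr", CONTINUOUS, [0.0, 5.0, 2.5])
    return table
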