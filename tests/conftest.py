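import numpy as np
import pytest

from edgemarker.io import ExpressionMatrix
from edgemarker.features import InteractionNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr():
    """4 genes x 6 samples, two classes of 3, strictly positive values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 7.0, 8.0, 9.0],   # shifted gene
            [5.0, 4.0, 6.0, 5.5, 4.5, 6.5],   # flat gene
            [1.0, 2.0, 3.0, 3.0, 2.0, 1.0],   # correlated with gA in class X only
            [2.0, 2.5, 3.5, 1.0, 3.0, 2.0],
        ]
    )
    samples = [f"s{i}" for i in range(1, 7)]
    labels = {s: ("X" if i < 3 else "Y") for i, s in enumerate(samples)}
    return ExpressionMatrix(["gA", "gB", "gC", "gD"], samples, values, labels)


@pytest.fixture
def small_net():
    return InteractionNetwork.from_pairs([("gA", "gB"), ("gA", "gC"), ("gB", "gD")])
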