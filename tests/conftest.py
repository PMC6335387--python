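import numpy as np
import pytest

from raschfit.datagen import (
    GeneratingModelSpec,
    ItemParameters,
    ResponseMatrix,
    draw_item_difficulties,
    generate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rasch_matrix(rng):
    """A moderate Rasch dataset (N=300, n=10) for estimation tests."""
    items = draw_item_difficulties(10, rng)
    return generate(GeneratingModelSpec("rasch"), 300, items, rng), items


@pytest.fixture
def small_matrix():
    """A fixed 8-person, 3-item matrix with non-degenerate columns."""
    data = np.array([
        [1, 0, 1],
        [0, 1, 1],
        [1, 1, 0],
        [1, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 1, 1],
        [1, 0, 1],
    ])
    return ResponseMatrix(data=data)
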