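import warnings

import numpy as np
import pytest

from pillarsim import ArrangementSpec, make_layout
from pillarsim.arrangements import PillarLayout


@pytest.fixture(scope="session")
def fractal_layout():
    return make_layout(ArrangementSpec("fractal"))


@pytest.fixture(scope="session")
def array_layout():
    return make_layout(ArrangementSpec("array"))


@pytest.fixture(scope="session")
def bulk_layout():
    return make_layout(ArrangementSpec("bulk"))


@pytest.fixture(scope="session")
def block_layout():
    """Factory: block layout for (n, d), with the n=9 count warning silenced."""

    cache = {}

    def _make(n: int, d: int) -> PillarLayout:
        if (n, d) not in cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cache[(n, d)] = make_layout(
                    ArrangementSpec("block", block_n=n, intra_block_gap=d)
                )
        return cache[(n, d)]

    return _make


def make_custom_layout(obstacle_mask: np.ndarray) -> PillarLayout:
    """A synthetic layout from a hand-built obstacle mask (tests only)."""
    spec = ArrangementSpec("bulk", field_size=obstacle_mask.shape[0], pillar_radius=1)
    return PillarLayout(obstacle_mask.copy(), np.empty((0, 2), dtype=np.int64), spec)
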