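import numpy as np
import pandas as pd
import pytest

from cpglights import synthetic_data as sd
from cpglights.motif_models import MotifAlignment, PositionCountMatrix


@pytest.fixture
def toy_alignment() -> MotifAlignment:
    """Four sequences, three columns — small enough for hand computation."""
    return MotifAlignment("TOY", ("ACG", "ACG", "ATG", "CCG"))


@pytest.fixture
def degenerate_alignment() -> MotifAlignment:
    return MotifAlignment("DEG", tuple(["TACGCA"] * 15))


@pytest.fixture
def tiny_sim_config() -> sd.SimulationConfig:
    return sd.SimulationConfig(
        n_classes=10,
        n_normal=6,
        n_tss=30,
        n_cpg_per_promoter=6.0,
        samples_per_class=2,
        seed=1234,
    )


def random_pcm(rng: np.random.Generator, length: int, n: float = 100.0) -> PositionCountMatrix:
    raw = rng.dirichlet(np.ones(4), size=length).T * n
    return PositionCountMatrix("RND", raw, n)
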