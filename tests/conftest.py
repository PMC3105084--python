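import numpy as np
import pytest

from plastcomp.simulate import (
    SimulationConfig,
    bamboo_like_config,
    simulate,
    toy_architecture,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng, n, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(20211)


@pytest.fixture(scope="session")
def toy_sim():
    """Small 4-taxon simulation used across modules."""
    cfg = SimulationConfig(
        tree="((A:0.01,B:0.01)AB:0.02,(C:0.01,D:0.01)CD:0.02);",
        architecture=toy_architecture(),
        seed=42,
    )
    return simulate(cfg, seed=42)


@pytest.fixture(scope="session")
def bamboo_sim():
    """Study-shaped 8-taxon simulation at reduced scale."""
    return simulate(bamboo_like_config(scale=0.3), seed=11)
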