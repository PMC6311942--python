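import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from mirlnc.io_data import InteractionNetwork
from mirlnc.synthetic import GeneratorConfig, generate


@pytest.fixture
def toy_net() -> InteractionNetwork:
    """2 miRNAs x 3 lncRNAs with 3 observed pairs."""
    return InteractionNetwork(
        ["m1", "m2"], ["l1", "l2", "l3"], {(0, 0), (0, 1), (1, 0)}
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """Default planted-block dataset (60 x 100, 4 blocks, seed 7)."""
    return generate(GeneratorConfig())


@pytest.fixture(scope="session")
def tiny_synthetic():
    """A fast 12 x 20 planted dataset for training-loop tests."""
    return generate(GeneratorConfig(nm=12, nl=20, n_blocks=2, p_in=0.5, p_out=0.1, seed=3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_model(rng, nm=5, nl=6, d=3, **hyper_kw):
    from mirlnc.model import Hyperparams, RankingModel

    h = Hyperparams(d=d, seed=0, **hyper_kw)
    return RankingModel(
        U=rng.normal(size=(nm, d)),
        V=rng.normal(size=(nl, d)),
        b=rng.normal(size=nl),
        hyper=h,
        mirna_ids=[f"m{i}" for i in range(nm)],
        lncrna_ids=[f"l{j}" for j in range(nl)],
    )
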