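from __future__ import annotations

import numpy as np
import pytest

from cnmskit.simulate import SimConfig, simulate_upstream_set


@pytest.fixture(scope="session")
def bundle42():
    """Default synthetic multi-species bundle, seed 42."""
    return simulate_upstream_set(SimConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_dna(rng: np.random.Generator, length: int,
               alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
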