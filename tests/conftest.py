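import numpy as np
import pytest

from pggpunish import GameConfig


@pytest.fixture
def lab_config() -> GameConfig:
    """The cited experiments' game: N=4, per-capita return 0.4, e=3, E=20."""
    return GameConfig(N=4, r=1.6, e=3.0, E=20.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_valid_config(rng, n_max: int = 8, e_max: float = 6.0) -> GameConfig:
    """Draw a game configuration satisfying the social-dilemma and
    punishment-efficiency constraints."""
    N = int(rng.integers(3, n_max + 1))
    e = float(rng.uniform(1.1, e_max))
    r = float(rng.uniform(1.05, N - 0.05))
    return GameConfig(N=N, r=r, e=e, E=20.0)
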