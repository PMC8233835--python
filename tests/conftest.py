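from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

import bbbassay as bbb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def corning():
    return bbb.get_format("96tw_corning")


@pytest.fixture
def twelve_tw():
    return bbb.get_format("12tw")


def simulate_batch(config: bbb.SimulationConfig, n_cells: int, n_blanks: int = 3, seed: int = 0):
    """Simulated cell and blank wells with independent per-well seeds."""
    rng = np.random.default_rng(seed)

    def sub() -> int:
        return int(rng.integers(0, 2**31 - 1))

    cells = [
        bbb.simulate_timecourse(replace(config, seed=sub()), with_cells=True)
        for _ in range(n_cells)
    ]
    blanks = [
        bbb.simulate_timecourse(replace(config, seed=sub()), with_cells=False)
        for _ in range(n_blanks)
    ]
    return cells, blanks
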