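import warnings

import numpy as np
import pandas as pd
import pytest

from aperislope.slope import SlopeMaps
from aperislope.synth import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Smallest config that exercises every pipeline stage."""
    return SimConfig(n_participants=3, n_trials_per_cell=6, rng_seed=11)


def generator_slope_maps(config: SimConfig) -> SlopeMaps:
    """Condition-averaged slope maps from the generator, via the full
    preprocessing + slope estimation chain (participant by participant)."""
    from aperislope.pipeline import RunConfig, compute_slope_maps

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        maps, _, _ = compute_slope_maps(RunConfig(sim=config))
    return maps


def make_toy_trials(
    rts=None, correct=None, n=12, participant=1, block=1,
):
    """A single-block trial table in printed-toy style: trial 1 is the first
    of the block, labels alternate to keep lag-1 consistency."""
    labels = ["congruent", "incongruent"] * (n // 2 + 1)
    curr = labels[:n]
    prev = ["incongruent"] + curr[:-1]
    rts = list(rts) if rts is not None else [500.0] * n
    correct = list(correct) if correct is not None else [True] * n
    return pd.DataFrame(
        {
            "participant": participant,
            "block": block,
            "trial_index": np.arange(1, n + 1),
            "is_practice": False,
            "is_first_of_block": [True] + [False] * (n - 1),
            "prev_congruency": prev,
            "curr_congruency": curr,
            "rt_ms": rts,
            "correct": correct,
            "rsi_ms": 1000.0,
        }
    )
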