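import numpy as np
import pytest

from anesnet.simdata import SimulationConfig, simulate_state_run
from anesnet.containers import CarpetMatrix


@pytest.fixture(scope="session")
def burst_run():
    """One high-SNR burst-suppression run with its ground truth."""
    cfg = SimulationConfig(state="burst_suppression", seed=7, run_length_volumes=300)
    return simulate_state_run(cfg)


@pytest.fixture(scope="session")
def awake_run():
    """One awake-like run (block covariance) with planted modules."""
    cfg = SimulationConfig(state="awake_like", n_nodes=24, run_length_volumes=240, seed=11)
    return simulate_state_run(cfg)


@pytest.fixture(scope="session")
def mixed_state_carpet():
    """Concatenated carpet with one 5-min run per planted state.

    Returns (carpet, planted state labels per run).
    """
    states = ["no_bursts", "single_burst", "burst_suppression", "no_suppressions"]
    blocks, bounds, cursor = [], [], 0
    for i, st in enumerate(states):
        cfg = SimulationConfig(state=st, seed=100 + i, run_length_volumes=150)
        carpet, _ = simulate_state_run(cfg)
        blocks.append(carpet.data)
        bounds.append((cursor, cursor + 150))
        cursor += 150
    carpet = CarpetMatrix(np.concatenate(blocks, axis=1), tr_seconds=2.0,
                          run_boundaries=bounds)
    return carpet, states
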