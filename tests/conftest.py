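"""Shared fixtures: expensive Brownian-dynamics runs are session-scoped."""

import numpy as np
import pytest

from porekinetics import synthetic_pore as sp


@pytest.fixture(scope="session")
def bd_equilibrium_run():
    """10^6-step equilibrium (V=0) run on the paper2Ca landscape, seed 1.

    Shared by the free-energy-recovery and detailed-balance (KS) tests.
    """
    cfg = sp.BDConfig(landscape=sp.preset_landscape("paper2Ca"),
                      n_steps=1_000_000, seed=1)
    return sp.simulate(cfg=cfg), cfg


@pytest.fixture(scope="session")
def random_walk_traces():
    """1000 synthetic path-coordinate traces exercising every crossing pattern.

    A mixture of small-step walks (slow traversals), large-step walks
    (fast traversals and occasional direct bulk-to-bulk jumps) and strongly
    drifting walks, all seeded.
    """
    rng = np.random.default_rng(2024)
    traces = []
    for k in range(1000):
        n = 400
        kind = k % 4
        if kind == 0:
            steps = rng.normal(0.0, 4.0, n)
        elif kind == 1:
            steps = rng.normal(0.0, 14.0, n)   # can jump bulk-to-bulk
        elif kind == 2:
            steps = rng.normal(0.8, 5.0, n)    # outward drift
        else:
            steps = rng.normal(-0.8, 5.0, n)   # inward drift
        start = rng.uniform(-45.0, 45.0)
        trace = np.clip(start + np.cumsum(steps), -58.0, 58.0)
        traces.append(trace)
    return np.array(traces)  # (1000, 400)
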