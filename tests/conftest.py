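"""Shared fixtures.  Heavy simulations are session-scoped so the expensive
trajectories are produced once and shared across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from kinseq.pipeline import make_fixture, sample_markov_chain
from kinseq.simulate import IntegratorSpec, run_bd_toy, three_state_spec


@pytest.fixture(scope="session")
def toy_trajectory():
    """Three-well BD trajectory: 10^5 saved frames (10^6 Euler steps).

    kT = 0.08 puts the inter-well saddles (~0.2 energy units above the
    minima) at ~2.5-3 kT, giving clear metastability with hundreds of
    transitions per 10^5 frames.
    """
    integ = IntegratorSpec(dt=0.01, n_steps=1_000_000, save_stride=10,
                           kT=0.08, seed=42)
    return run_bd_toy(three_state_spec(), integ)


@pytest.fixture(scope="session")
def active_polymer_ensemble():
    """Ensemble of active-chain trajectories from the wound-spiral start.

    24 members x 3x10^6 Euler steps at dt = 0.001 tau_BD (3,000 tau_BD each,
    saved every 100 steps): the spiral state's breakup time is of order
    3x10^3 tau_BD, so a majority of members convert to the extended state
    within the run and both basins are well sampled.
    """
    from kinseq.pipeline import active_polymer_ensemble as build

    return build(master_seed=2024)


@pytest.fixture(scope="session")
def markov3_sequence():
    """3-state Markov-chain token sequence with known transition matrix."""
    T = np.array([[0.90, 0.08, 0.02], [0.10, 0.80, 0.10], [0.05, 0.15, 0.80]])
    tokens = sample_markov_chain(T, 60_000, seed=5)
    return tokens, T


@pytest.fixture(scope="session")
def second_order_sequence():
    """3-state chain whose next token depends on the previous two."""
    return make_fixture("second_order", {"n": 60_000, "p_follow": 0.9}, seed=9)
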