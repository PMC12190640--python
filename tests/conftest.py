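"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import ribofret as rf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_nomg_dataset():
    """30 molecules from the zero-Mg occupancy fixture (dynamic, 3-state)."""
    fixture = rf.get_fixture("noMg_occupancy")
    return rf.generate_dataset(fixture, 30, seed=91)


@pytest.fixture(scope="session")
def small_kinetics_dataset():
    """40 molecules from the zero-Mg two-state kinetics fixture."""
    fixture = rf.get_fixture("noMg_kinetics")
    return rf.generate_dataset(fixture, 40, seed=92)


def two_state_trace(
    n_frames: int = 1000,
    centers=(0.2, 0.8),
    sigma: float = 0.07,
    k12: float = 0.1,
    k21: float = 0.1,
    seed: int = 0,
    total: float = 1000.0,
    noise: float = 40.0,
    frame_rate: float = 10.0,
) -> rf.Trace:
    """Small two-state trace generator used across test modules."""
    emission = rf.EmissionModel(
        state_centers=tuple(centers),
        state_sigma=(sigma,) * len(centers),
        total_intensity=total,
        intensity_sigma=noise,
    )
    rates = rf.two_state_rates(k12, k21)
    rng = np.random.default_rng(seed)
    duration = n_frames / frame_rate
    cps, states = rf.simulate_state_path(rates, duration, rng)
    occ = rf.discretize_path(cps, states, 2, duration, 1.0 / frame_rate)
    return rf.emit_trace(occ, emission, rng, "two_state", frame_rate)
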