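"""Shared fixtures: small deterministic inputs used across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from calcipair import SimulationBox, ThermoState, Trajectory


@pytest.fixture(scope="session")
def thermo() -> ThermoState:
    return ThermoState(temperature=330.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def small_box() -> SimulationBox:
    return SimulationBox.cubic(10.0)


@pytest.fixture()
def tiny_trajectory(small_box) -> Trajectory:
    """Two-frame, three-particle trajectory with fixed coordinates."""
    positions = np.array(
        [
            [[1.0, 1.0, 1.0], [4.0, 1.0, 1.0], [1.0, 5.0, 1.0]],
            [[1.1, 1.0, 1.0], [4.1, 1.0, 1.0], [1.0, 5.1, 1.0]],
        ]
    )
    return Trajectory(
        species=("Ca", "O", "O"),
        positions=positions,
        times=np.array([0.0, 0.5]),
        box=small_box,
        wrapped=True,
    )
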