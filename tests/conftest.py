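"""Shared fixtures: small hand-built cell states and seeded initializations."""

from __future__ import annotations

import math

import numpy as np
import pytest

from epiboly import Config, SimulationState, initialize


@pytest.fixture(scope="session")
def default_config() -> Config:
    return Config(seed=0)


def make_ring_state(
    n: int = 6,
    phi: float = math.pi / 2,
    radius: float = 3.09,
    cell_radius: float = 0.158,
    interior_rows: int = 0,
) -> SimulationState:
    """A margin ring of ``n`` cells at polar angle ``phi``, optionally backed
    by rows of internal cells at smaller polar angles, bonded ring-wise and
    row-to-row."""
    rows = []
    kinds = []
    dphi = 2.0 * cell_radius / radius
    for r in range(interior_rows + 1):
        ph = phi - r * dphi
        theta = np.arange(n) * (2.0 * math.pi / n)
        pts = radius * np.stack(
            [
                np.sin(ph) * np.cos(theta),
                np.sin(ph) * np.sin(theta),
                np.full(n, np.cos(ph)),
            ],
            axis=1,
        )
        rows.append(pts)
        kinds.extend([r == 0] * n)
    pos = np.vstack(rows)
    m = len(pos)
    state = SimulationState(
        positions=pos,
        cell_radii=np.full(m, cell_radius),
        drags=np.ones(m),
        is_margin=np.array(kinds, dtype=bool),
        particle_radius=0.09,
        yolk_radius=3.0,
    )
    for r in range(interior_rows + 1):
        base = r * n
        for i in range(n):
            if r == 0:
                state.add_bond(base + i, base + (i + 1) % n)  # ring bonds
            if r < interior_rows:
                state.add_bond(base + i, base + n + i)
                state.add_bond(base + i, base + n + (i + 1) % n)
            elif r > 0:
                state.add_bond(base + i, base + (i + 1) % n)
    return state


@pytest.fixture
def hex_ring_state() -> SimulationState:
    return make_ring_state(n=6)


@pytest.fixture
def layered_state() -> SimulationState:
    return make_ring_state(n=24, interior_rows=3)


@pytest.fixture(scope="session")
def initialized_state(default_config) -> SimulationState:
    """One seeded full-size initialization, shared across tests."""
    return initialize(default_config, np.random.default_rng(42))
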