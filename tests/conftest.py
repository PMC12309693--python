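"""Shared fixtures: small meshes, random-mesh factory, cached scenario runs."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

import midlinesim as ms
from midlinesim.assembly import scenario


@pytest.fixture()
def unit_square_mesh() -> ms.TissueMesh:
    """One unit-square cell: (0,0), (1,0), (1,1), (0,1)."""
    return ms.TissueMesh(
        np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
        np.array([[0, 1, 2, 3]]),
    )


@pytest.fixture()
def chain8() -> ms.TissueMesh:
    return ms.make_initial_mesh(8)


def random_mesh(seed: int, n_cells: int = 8, jitter: float = 0.08) -> ms.TissueMesh:
    """Fresh chain with jittered vertices (still simple/positively oriented)."""
    rng = np.random.default_rng(seed)
    mesh = ms.make_initial_mesh(n_cells)
    mesh.vertices += jitter * rng.standard_normal(mesh.vertices.shape)
    mesh.validate()
    return mesh


@lru_cache(maxsize=None)
def _scenario_cached(name: str, tethered: bool, seed: int, t_end: float, overrides: tuple):
    return scenario(name, tethered=tethered, seed=seed, t_end=t_end, **dict(overrides))


def run_scenario(name, tethered=True, seed=0, t_end=100.0, **overrides):
    """Memoized scenario run shared across tests in one session."""
    return _scenario_cached(name, tethered, seed, t_end, tuple(sorted(overrides.items())))


@pytest.fixture(scope="session")
def scenario_runner():
    return run_scenario
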