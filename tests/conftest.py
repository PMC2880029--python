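import numpy as np
import pytest

from beadqc.array_model import build_layout, build_neighbour_graph, nominal_positions
from beadqc.synthetic import SimulationConfig, simulate_section


@pytest.fixture(scope="session")
def wg6_layout():
    return build_layout("WG6v2")


@pytest.fixture()
def small_grid(wg6_layout):
    """7x8 pitch-6 hexagonal lattice with origin (20, 20)."""
    return nominal_positions(wg6_layout, (20.0, 20.0), rows=7, cols=8)


@pytest.fixture()
def small_graph(small_grid):
    return build_neighbour_graph(small_grid)


@pytest.fixture(scope="session")
def clean_section():
    """One rendered artefact-free section, reused by extraction/registration tests."""
    cfg = SimulationConfig(seed=11, rows=40, cols=40, n_bead_types=80)
    return simulate_section(cfg)


def brute_force_neighbours(grid):
    """Oracle: adjacency by pairwise distance == pitch (within 1e-9)."""
    n = grid.n
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(grid.x[i] - grid.x[j], grid.y[i] - grid.y[j])
            if abs(d - grid.pitch) < 1e-9:
                adj[i].add(j)
                adj[j].add(i)
    return adj
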