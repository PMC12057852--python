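from __future__ import annotations

import numpy as np
import pytest

from krqol import SimulationConfig, default_variable_specs, simulate_cohort
from krqol.discretize import Item, ItemMatrix


@pytest.fixture(scope="session")
def specs():
    return default_variable_specs()


@pytest.fixture(scope="session")
def demo_cohort():
    """One default synthetic cohort (N=44), reused across read-only tests."""
    return simulate_cohort(SimulationConfig(seed=1))


def random_item_matrix(
    rng: np.random.Generator, n: int, n_vars: int, p_high: float | None = None
) -> ItemMatrix:
    """A random dichotomized matrix: two complementary items per variable."""
    items: list[Item] = []
    cols = []
    for v in range(n_vars):
        p = rng.uniform(0.2, 0.8) if p_high is None else p_high
        high = rng.random(n) < p
        items += [Item(f"v{v}", "high"), Item(f"v{v}", "low")]
        cols += [high, ~high]
    return ItemMatrix(
        participants=[f"P{i}" for i in range(n)],
        items=items,
        membership=np.column_stack(cols),
    )
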