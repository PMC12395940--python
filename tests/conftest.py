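import numpy as np
import pandas as pd
import pytest

from arealna import from_edge_list, preset_scenario, simulate
from arealna.areas import STRATA


def grid_edge_list(rows, cols):
    """Rook-lattice edges on row-major unit ids g0, g1, ..."""
    ids = [f"g{i}" for i in range(rows * cols)]
    pairs = []
    for i in range(rows):
        for j in range(cols):
            k = i * cols + j
            if j + 1 < cols:
                pairs.append((ids[k], ids[k + 1]))
            if i + 1 < rows:
                pairs.append((ids[k], ids[k + cols]))
    return pairs, ids


@pytest.fixture
def grid3x3():
    pairs, ids = grid_edge_list(3, 3)
    return from_edge_list(pairs, ids)


@pytest.fixture
def grid10x10():
    pairs, ids = grid_edge_list(10, 10)
    return from_edge_list(pairs, ids)


@pytest.fixture
def path3():
    return from_edge_list([("A", "B"), ("B", "C")], ["A", "B", "C"])


def make_area_table(n, seed=0, with_x=True):
    """Small hand-rolled area table with valid counts."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"unit_id": [f"a{i}" for i in range(n)]})
    for s in STRATA:
        df[f"pop_{s}"] = rng.integers(500, 2000, size=n)
    for prefix, scale in (("y_inc", 0.01), ("y_mort", 0.005)):
        for s in STRATA:
            df[f"{prefix}_{s}"] = rng.poisson(df[f"pop_{s}"] * scale)
    if with_x:
        df["x"] = rng.uniform(0, 10, size=n)
    return df


@pytest.fixture
def area_table():
    return make_area_table(12, seed=1)


@pytest.fixture(scope="session")
def unconfounded_data():
    areas, W = simulate(preset_scenario("unconfounded", seed=42))
    return areas, W


@pytest.fixture(scope="session")
def confounded_data():
    areas, W = simulate(preset_scenario("confounded", seed=7))
    return areas, W
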