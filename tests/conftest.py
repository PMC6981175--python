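import numpy as np
import pandas as pd
import pytest

import adfield as a


def grid_table(positions, **layers):
    """Grid table from integer lattice positions (centers at +0.5)."""
    df = pd.DataFrame(
        {
            "cell_id": np.arange(len(positions)),
            "lon": [p[0] + 0.5 for p in positions],
            "lat": [p[1] + 0.5 for p in positions],
        }
    )
    for name, vals in layers.items():
        df[name] = vals
    return df


@pytest.fixture
def strip_domain():
    """Three collinear cells A=0, B=1, C=2 along the x axis."""
    return a.build_domain(grid_table([(0, 0), (1, 0), (2, 0)]))


@pytest.fixture
def toy_P():
    """sp1={A,B}, sp2={B,C}, sp3={B} on the 3-cell strip."""
    return a.PresenceAbsence.from_dense(
        np.array([[1, 1, 0], [0, 1, 1], [0, 1, 0]]),
        species=["sp1", "sp2", "sp3"],
    )


@pytest.fixture
def block3x3():
    return a.build_domain(
        grid_table([(i, j) for i in range(3) for j in range(3)])
    )


def random_presence(rng, max_species=50, max_cells=100):
    """Random binary matrix with no empty species rows."""
    S = int(rng.integers(1, max_species + 1))
    N = int(rng.integers(2, max_cells + 1))
    m = (rng.random((S, N)) < rng.uniform(0.05, 0.6)).astype(int)
    for i in range(S):  # ensure r_i >= 1
        if m[i].sum() == 0:
            m[i, rng.integers(N)] = 1
    return m
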