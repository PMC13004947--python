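import numpy as np
import pandas as pd
import pytest


def make_table(positions_per_traj):
    """Long trajectory table from a list of (N_i, 2) position arrays (µm)."""
    rows = []
    for i, pos in enumerate(positions_per_traj):
        pos = np.asarray(pos, float)
        for f, (x, y) in enumerate(pos):
            rows.append((i, f, x, y))
    return pd.DataFrame(rows, columns=["trajectory", "frame", "x", "y"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
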