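import numpy as np
import pandas as pd
import pytest

from patterngene.preprocess import RawExpressionTable


@pytest.fixture
def rng():
    return np.random.default_rng(20131202)


@pytest.fixture
def random_profiles(rng):
    """1,000 random nonnegative profiles of varying length for property checks."""

    def make(count=1000, n_min=2, n_max=50):
        out = []
        while len(out) < count:
            n = int(rng.integers(n_min, n_max + 1))
            x = rng.gamma(shape=1.0, scale=100.0, size=n)
            x[rng.random(n) < 0.2] = 0.0  # sprinkle true zeros
            if (x > 0).any():
                out.append(x)
        return out

    return make


@pytest.fixture
def raw_table():
    """A small probeset table with flags and a probe map, two replicate columns."""
    values = pd.DataFrame(
        {
            "liver": [5.0, 1.0, 2.0, 7.2],
            "brain_1": [5.0, 9.0, 4.0, 0.0],
            "brain_2": [5.0, 9.0, 4.0, 0.0],
            "heart": [5.0, 5.0, 6.0, 3.0],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="id"),
    )
    flags = pd.DataFrame(
        [list("PPPP"), list("PPPP"), list("PPPP"), list("APPM")],
        index=values.index,
        columns=values.columns,
    )
    probe_map = {"p1": "G1", "p2": "G2", "p3": "G2", "p4": "G3"}
    return RawExpressionTable(values=values, flags=flags, probeset_to_gene=probe_map)
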