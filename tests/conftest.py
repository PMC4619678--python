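import numpy as np
import pandas as pd
import pytest

from standstruct import PlotPattern, PlotWindow


@pytest.fixture
def window():
    return PlotWindow(0, 50, 0, 50)


def make_pattern(x, y, dbh=None, species=None, window=None, code="T",
                 height=None, lat=None):
    """Build a plot pattern from bare arrays with sensible defaults."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    trees = pd.DataFrame({
        "x": x,
        "y": np.asarray(y, dtype=float),
        "species": species if species is not None else ["SP1"] * n,
        "dbh": dbh if dbh is not None else [20.0] * n,
    })
    if height is not None:
        trees["height"] = height
    return PlotPattern(code=code, window=window or PlotWindow(),
                       trees=trees, lat=lat)


@pytest.fixture
def csr_pattern(window):
    rng = np.random.default_rng(1234)
    return make_pattern(rng.uniform(0, 50, 80), rng.uniform(0, 50, 80),
                        window=window)
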