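import numpy as np
import pandas as pd
import pytest

import crosslag as cl
from crosslag.procsim import Panel


@pytest.fixture
def tradeoff_panel():
    """A moderate trade-off panel with among-subject covariance."""
    return cl.simulate(cl.default_spec("tradeoff_multi", n_subjects=60,
                                       n_time=10, seed=101))


@pytest.fixture
def grouplive_panel():
    return cl.simulate(cl.default_spec("grouplive_multi", n_subjects=60,
                                       n_time=10, seed=202))


@pytest.fixture
def single_series_panel():
    return cl.simulate(cl.default_spec("tradeoff_single", n_time=40, seed=303))


@pytest.fixture
def tiny_panel():
    """Handcrafted two-subject panel for exact arithmetic checks."""
    df = pd.DataFrame({
        "subject": [1, 1, 2, 2],
        "time": [1, 2, 1, 2],
        "X": [1.0, 3.0, 10.0, 14.0],
        "Y": [0.5, 1.5, 3.0, 5.0],
    })
    return Panel(df)
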