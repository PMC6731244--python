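import numpy as np
import pandas as pd
import pytest

from metnetkit.metabolomics_stats import OmicsTable
from metnetkit.synthetic import make_toy_database


@pytest.fixture(scope="session")
def toy_db():
    return make_toy_database("tca+glycolysis+bcaa")


@pytest.fixture(scope="session")
def tca_db():
    return make_toy_database("tca")


def make_table(values: dict[str, list[float]], conditions: dict[str, str],
               scale: str = "raw") -> OmicsTable:
    """Tiny OmicsTable from literal rows; NaN marks missing."""
    frame = pd.DataFrame(values).T
    frame.columns = list(conditions)
    return OmicsTable(
        values=frame.astype(float),
        conditions=pd.Series(conditions),
        scale=scale,
    )


@pytest.fixture
def small_table():
    # 3 features x 6 samples, two conditions, one missing cell
    return make_table(
        {
            "malate": [4.0, np.nan, 8.0, 10.0, 12.0, 14.0],
            "citrate": [5.0, 5.0, 5.0, 20.0, 22.0, 24.0],
            "leucine": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
        },
        {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"},
    )
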