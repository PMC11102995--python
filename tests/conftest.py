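import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dmindex.delphi import DIMENSIONS, DelphiScoreTable

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from dmindex.index_model import table5_fixture


@pytest.fixture(scope="session")
def fixture_index():
    """The packaged 6-domain / 56-leaf index with published weights."""
    return table5_fixture()


@pytest.fixture(scope="session")
def tree(fixture_index):
    return fixture_index[0]


@pytest.fixture(scope="session")
def bundle(fixture_index):
    return fixture_index[1]


def make_score_table(matrix, indicators=None, dims=DIMENSIONS) -> DelphiScoreTable:
    """Build a DelphiScoreTable from an (experts x indicators) array, using
    the same scores for every dimension."""
    matrix = np.asarray(matrix, dtype=float)
    m, n = matrix.shape
    indicators = indicators or [f"ind_{j}" for j in range(n)]
    cols = pd.MultiIndex.from_product([indicators, dims], names=["indicator", "dimension"])
    data = np.repeat(matrix, len(dims), axis=1)
    df = pd.DataFrame(data, columns=cols, index=[f"expert_{i}" for i in range(m)])
    return DelphiScoreTable(df)
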