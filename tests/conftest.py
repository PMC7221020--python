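import numpy as np
import pandas as pd
import pytest

from mapstrat import CohortSpec, MutationMatrix, load_rules
from mapstrat.panel import PANEL


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def paper_spec():
    return CohortSpec.paper_default(seed=7)


@pytest.fixture
def toy_matrix():
    """A: KRAS only; B: KRAS+TP53; C: no mutations."""
    df = pd.DataFrame(0, index=["A", "B", "C"], columns=list(PANEL), dtype=np.int8)
    df.loc["A", "KRAS"] = 1
    df.loc["B", ["KRAS", "TP53"]] = 1
    return MutationMatrix(df)


def random_matrix(rng, n=40, p=0.2, genes=PANEL):
    arr = (rng.random((n, len(genes))) < p).astype(np.int8)
    return MutationMatrix.from_array(arr, genes=list(genes))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
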