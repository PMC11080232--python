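import numpy as np
import pandas as pd
import pytest

from rumivirome.simulate import SimConfig, simulate_community
from rumivirome.types import AbundanceTable


@pytest.fixture(scope="session")
def community():
    """A fixed synthetic community shared by read-only tests."""
    return simulate_community(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_table(counts, sample_ids=None, taxa=None, value_kind="read_count", **kw):
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"s{i}" for i in range(counts.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(counts.shape[1])]
    return AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxa), value_kind, **kw
    )
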