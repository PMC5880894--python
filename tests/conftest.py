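import numpy as np
import pytest

from cyanoniche.datamodel import CountTable, EnvMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    return CountTable(
        taxon_ids=["t1", "t2", "t3"],
        sample_ids=["s1", "s2"],
        counts=np.array([[1, 2], [0, 5], [3, 0]]),
    )


@pytest.fixture
def env_two_samples():
    return EnvMatrix(
        sample_ids=["s1", "s2"],
        variables=["PP", "PN", "DP", "DN", "precipitation", "temperature"],
        values=np.arange(12, dtype=float).reshape(2, 6),
    )


def write_tsv(path, text):
    path.write_text(text)
    return path
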