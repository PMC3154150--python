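import numpy as np
import pytest

from epiforge import ContingencyTable, init_dataset, to_contingency


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_table(rng, n_subjects=60, n_snps=3) -> ContingencyTable:
    """A small random balanced table for oracle comparisons."""
    return to_contingency(init_dataset(n_subjects, n_snps, rng))
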