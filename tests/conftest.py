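import numpy as np
import pandas as pd
import pytest

from thermophos.quant import AbundanceMatrix, Thresholds


def make_matrix(rows):
    """rows: (accession, condition, replicate, intensity, noise)."""
    return AbundanceMatrix(pd.DataFrame(
        rows, columns=list(AbundanceMatrix.COLUMNS)))


def matrix_from_log2(profiles, noise=1.0):
    """profiles: {accession: {condition: [log2 intensities]}}."""
    rows = []
    for acc, conds in profiles.items():
        for cond, vals in conds.items():
            for rep, v in enumerate(vals, start=1):
                rows.append((acc, cond, rep,
                             np.nan if v is None else 2.0 ** v, noise))
    return make_matrix(rows)


@pytest.fixture
def thresholds():
    return Thresholds()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
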