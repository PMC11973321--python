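import numpy as np
import pandas as pd
import pytest

from crcpod.io_tables import AbundanceTable, SampleMetadata


def make_table(values, taxa=None, samples=None, scale="percent", rank="species"):
    """Small AbundanceTable from a taxa × samples array."""
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"s__T{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return AbundanceTable(pd.DataFrame(values, index=taxa, columns=samples),
                          rank=rank, scale=scale)


def make_metadata(sample_ids, groups, cohort="c1", **covariates):
    frame = pd.DataFrame({"cohort": cohort, "group": list(groups), **covariates},
                         index=pd.Index(list(sample_ids), name="sample_id"))
    return SampleMetadata(frame)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    # column sums 90 and 110: legal by default, rejected in strict percent mode
    return make_table([[60.0, 40.0], [30.0, 70.0]])
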