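import numpy as np
import pandas as pd
import pytest

from codysbiosis import AbundanceTable, SampleMetadata


@pytest.fixture
def small_table() -> AbundanceTable:
    """4 samples x 4 taxa (2 bacteria, 2 fungi), raw counts."""
    data = pd.DataFrame(
        {
            "Bact1": [2.0, 1.0, 4.0, 0.0],
            "Bact2": [2.0, 3.0, 0.0, 5.0],
            "Fung1": [1.0, 2.0, 1.0, 1.0],
            "Fung2": [3.0, 0.0, 3.0, 2.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    kingdom = pd.Series(
        ["bacteria", "bacteria", "fungi", "fungi"], index=data.columns
    )
    rank = pd.Series("genus", index=data.columns)
    return AbundanceTable(data, kingdom, rank)


@pytest.fixture
def small_metadata() -> SampleMetadata:
    frame = pd.DataFrame(
        {
            "group": ["ARFC", "ARFC", "HC", "HC"],
            "age": [4.0, 5.0, 4.5, 5.5],
            "sex": ["M", "F", "M", "F"],
            "total_ige": [300.0, 250.0, 60.0, 70.0],
            "sIgE_house_dust_mite": [2.5, 1.0, 0.1, 0.2],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return SampleMetadata(frame)


def two_group_table(n_per_group=10, n_bact=5, n_fungi=5, seed=0):
    """Random fraction table + metadata for pipeline-level tests."""
    rng = np.random.default_rng(seed)
    samples = [f"A{i}" for i in range(n_per_group)] + [
        f"B{i}" for i in range(n_per_group)
    ]
    taxa = [f"Bact{i}" for i in range(n_bact)] + [f"Fung{i}" for i in range(n_fungi)]
    raw = rng.lognormal(size=(len(samples), len(taxa)))
    data = pd.DataFrame(raw, index=samples, columns=taxa)
    for cols in (taxa[:n_bact], taxa[n_bact:]):
        data[cols] = data[cols].div(data[cols].sum(axis=1), axis=0)
    kingdom = pd.Series(
        ["bacteria"] * n_bact + ["fungi"] * n_fungi, index=taxa
    )
    table = AbundanceTable(data, kingdom, pd.Series("genus", index=taxa),
                           normalized=True)
    meta = SampleMetadata(pd.DataFrame(
        {"group": ["ARFC"] * n_per_group + ["HC"] * n_per_group,
         "total_ige": rng.lognormal(4, 1, len(samples))},
        index=samples,
    ))
    return table, meta
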