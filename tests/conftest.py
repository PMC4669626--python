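import numpy as np
import pandas as pd
import pytest

from nannopop import Dataset, GenotypeMatrix, study_design_config, simulate_dataset


def make_dataset(calls, meta_rows, locus_prefix="L"):
    """Build a small Dataset from a call matrix and metadata dicts."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    ids = [row["sample_id"] for row in meta_rows]
    loci = [f"{locus_prefix}{j + 1}" for j in range(L)]
    g = GenotypeMatrix(ids, loci, calls, [("0", "1")] * L)
    return Dataset(g, pd.DataFrame(meta_rows))


def female_row(sid, colony="C1", pop="P1", x=0.0, y=0.0):
    return {
        "sample_id": sid,
        "category": "female",
        "population": pop,
        "colony": colony,
        "host_id": None,
        "x": x,
        "y": y,
    }


def male_row(sid, host, colony="C1", pop="P1", x=0.0, y=0.0):
    return {
        "sample_id": sid,
        "category": "dwarf_male",
        "population": pop,
        "colony": colony,
        "host_id": host,
        "x": x,
        "y": y,
    }


@pytest.fixture(scope="session")
def study_ds():
    """One study-design-like simulated dataset shared across tests."""
    ds, truth = simulate_dataset(study_design_config(), seed=7)
    return ds, truth
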