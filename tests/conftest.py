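import numpy as np
import pytest

from edsel import SimConfig, SpeciesTriplet, simulate_dataset
from edsel.ancestry import build_substitution_matrix, pool_matrices

TRIPLETS = [
    SpeciesTriplet("focal", "sister", "outgroup"),
    SpeciesTriplet("sister", "focal", "outgroup"),
    SpeciesTriplet("outgroup", "focal", "sister"),
]


def pooled_matrix(ds, transcripts=False, el_min=0.0):
    """Matrix pooled over the three focal-species choices of a triplet."""
    mats = [
        build_substitution_matrix(
            ds.alignments, t,
            transcripts=ds.transcripts[t.focal] if transcripts else None,
            el_min=el_min,
        )
        for t in TRIPLETS
    ]
    return pool_matrices(mats)


@pytest.fixture(scope="session")
def neutral_ds():
    """A mid-sized neutral dataset shared across tests."""
    return simulate_dataset(
        SimConfig(n_transcripts=120, mean_cds_len=600, editing_density=0.03, seed=101)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
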