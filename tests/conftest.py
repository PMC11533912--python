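import numpy as np
import pandas as pd
import pytest

from tapdose import biodistribution as bd
from tapdose import nuclide_chain as nc
from tapdose import synthetic_data as sd


@pytest.fixture(scope="session")
def chain() -> nc.DecayChain:
    return nc.pb212_chain()


@pytest.fixture(scope="session")
def emissions(chain) -> nc.EmissionSummary:
    return nc.chain_emission_summary(chain)


@pytest.fixture(scope="session")
def noiseless_table() -> bd.BiodistTable:
    """Deterministic biodistribution table at 28 and 280 ng."""
    scenario = sd.default_biodist_scenario(noise_cv=0.0, peptide_masses_ng=(28.0, 280.0))
    return sd.gen_biodist(scenario)


def simple_table(rows, standard_counts=1000.0, **kwargs) -> bd.BiodistTable:
    """Hand-built table from (animal, group, organ, mass_g, counts, count_t, tp) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["animal_id", "group", "organ", "mass_g", "counts", "count_time_h", "timepoint_h"],
    )
    return bd.BiodistTable(samples=df, standard_counts=standard_counts, **kwargs)
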