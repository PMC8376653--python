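import numpy as np
import pandas as pd
import pytest

from famcoaggr import simulate
from famcoaggr.catalog import default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """Medium synthetic cohort with latent draws, reused across read-only tests."""
    truth = simulate.AceTruth.from_variance_shares(
        0.5, 0.2, 0.4, 0.2, rA=0.4, rC=0.3, rE=0.2, prev1=0.05, prev2=0.10
    )
    spec = simulate.FamilySpec(
        n_fullsib_families=20000, n_halfsib_families=8000, seed=42
    )
    return simulate.simulate_ace_families(truth, spec, keep_latent=True)


def toy_persons(rows):
    """Build a persons table from (pid, mother, father, sex, byear, death, twin)."""
    return pd.DataFrame(
        rows,
        columns=[
            "person_id", "mother_id", "father_id", "sex",
            "birth_year", "death_emig_year", "is_twin",
        ],
    ).assign(family_id=0)
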