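import numpy as np
import pandas as pd
import pytest

from mcci import (
    MappingTable,
    SimulationConfig,
    assemble_cohort,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def mapping():
    return MappingTable.bundled()


@pytest.fixture(scope="session")
def small_sim():
    """A 4,000-patient synthetic claims bundle (fixed seed)."""
    return simulate_cohort(SimulationConfig(n_patients=4_000, seed=11))


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    return assemble_cohort(
        small_sim.claims, small_sim.demographics, small_sim.deaths
    ).cohort


def toy_claims():
    """Three-patient hand-written claims/demographics/deaths tables."""
    claims = pd.DataFrame(
        {
            "patient_id": ["A", "B", "C", "B"],
            "admission_month": ["2002-03", "2002-03", "2010-01", "2003-06"],
            "icd10_codes": ["I21;C78.7", "E11.2", "K25", "I50"],
        }
    )
    demographics = pd.DataFrame(
        {
            "patient_id": ["A", "B", "C"],
            "birth_year": [1950, 1970, 1990],
            "sex": ["male", "female", "male"],
            "region": ["metropolitan", "city_or_rural", "metropolitan"],
            "income_group": [0, 5, 10],
        }
    )
    deaths = pd.DataFrame(
        {"patient_id": ["A", "B"], "death_month": ["2002-03", "2003-03"]}
    )
    return claims, demographics, deaths
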