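import datetime as dt

import pandas as pd
import pytest

from cecscreen.model import ConcentrationRecord, SiteMaxMatrix
from cecscreen.simulate import GeneratorConfig, generate_registries, simulate_records

D1 = dt.date(2013, 5, 15)
D2 = dt.date(2013, 8, 20)


def rec(site, sample, chem, value, status, rl, matrix="water", date=D1):
    return ConcentrationRecord(
        site_id=site,
        sample_id=sample,
        collection_date=date,
        matrix=matrix,
        chemical_id=chem,
        value=value,
        detect_status=status,
        reporting_limit=rl,
    )


@pytest.fixture
def small_records():
    """Two sites x two visits x two chemicals in water, one sediment slot."""
    return [
        rec("S1", "S1-W1", "A", 0.5, "quantified", 0.04),
        rec("S1", "S1-W2", "A", 0.01, "estimated", 0.04, date=D2),
        rec("S1", "S1-W1", "B", None, "nondetect", 0.1),
        rec("S1", "S1-W2", "B", None, "nondetect", 0.1, date=D2),
        rec("S2", "S2-W1", "A", None, "nondetect", 0.04),
        rec("S2", "S2-W2", "A", 0.2, "quantified", 0.04, date=D2),
        rec("S2", "S2-W1", "B", 0.6, "quantified", 0.1),
        rec("S2", "S2-W2", "B", 0.4, "quantified", 0.1, date=D2),
        rec("S1", "S1-SED", "A", 120.0, "quantified", 40.0, matrix="sediment"),
    ]


@pytest.fixture
def site_max_2x2():
    values = pd.DataFrame(
        [[1.0, 0.0], [0.2, 3.0]],
        index=pd.Index(["S1", "S2"], name="site_id"),
        columns=pd.Index(["A", "B"], name="chemical_id"),
    )
    return SiteMaxMatrix(values, "water")


@pytest.fixture(scope="session")
def default_run():
    """One simulated dataset at generator defaults, shared across tests."""
    config = GeneratorConfig(seed=7)
    registries = generate_registries(config)
    records = simulate_records(registries, config)
    return config, registries, records
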