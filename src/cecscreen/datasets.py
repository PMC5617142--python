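"""Bundled reference tables.

``survey_frequent_chemicals.csv`` is the published per-chemical summary of
a 2013–14 basin-wide CEC survey of 12 Great Lakes tributaries (292 water
and 80 sediment samples): every chemical detected in at least 30% of the
samples of a matrix, with its class, log K_ow, reporting limit, sample
count, median, maximum, and detection frequency.  Medians below the
reporting limit are stored as missing (they were published only as
"<reporting limit").

``benchmarks_water.csv`` and ``guidelines_sediment.csv`` carry the
screening thresholds used alongside that survey: lowest chronic
aquatic-life water benchmarks (µg/L) and tiered TEC/MEC/PEC sediment
quality guidelines (µg/kg).

``eeq_factors_synthetic.csv`` is a synthetic example estrogenic-potency
table for exercising the EEQ machinery; it is not an authoritative
compilation and ships only so the pipeline runs without a user factor file.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_eeq_factors, read_sediment_guidelines, read_water_benchmarks
from .model import BenchmarkSet, SiteMaxMatrix

_DATA = resources.files(__package__) / "data"


def _path(name: str):
    return _DATA / name


def load_survey_summary(matrix: str) -> pd.DataFrame:
    """Published frequent-chemical summary for one matrix.

    Indexed by chemical_id with the same columns ``chemical_summary``
    produces (plus ``name``, ``chemical_class``, ``log_kow``), so the
    ubiquity filter and reporting helpers apply directly.
    """
    with resources.as_file(_path("survey_frequent_chemicals.csv")) as p:
        df = pd.read_csv(p)
    df = df[df["matrix"] == matrix].set_index("chemical_id")
    df["n_detected"] = (
        df["n_analyzed"] * df["detection_frequency"] / 100.0
    ).round().astype(int)
    return df


def load_survey_benchmarks() -> BenchmarkSet:
    """Water benchmarks and sediment guidelines as one BenchmarkSet."""
    with resources.as_file(_path("benchmarks_water.csv")) as p:
        water = read_water_benchmarks(p)
    with resources.as_file(_path("guidelines_sediment.csv")) as p:
        sediment = read_sediment_guidelines(p)
    return BenchmarkSet(water=water, sediment=sediment)


def load_synthetic_eeq_factors() -> dict:
    with resources.as_file(_path("eeq_factors_synthetic.csv")) as p:
        return read_eeq_factors(p)


def survey_basin_maxima(matrix: str) -> SiteMaxMatrix:
    """Basin-wide maxima from the survey summary as a one-row site-max
    matrix (pseudo-site ``BASIN``), for screening the published maxima
    against benchmarks."""
    summary = load_survey_summary(matrix)
    values = summary[["maximum"]].T.rename(index={"maximum": "BASIN"})
    values.index.name = "site_id"
    values.columns.name = "chemical_id"
    return SiteMaxMatrix(values.astype(float), matrix)
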