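"""Domain types for the CEC screening pipeline.

The pipeline operates on analytical results for trace organic contaminants
(pharmaceuticals, pesticides, sterols, PAHs, flame retardants, ...) measured
in surface water (µg/L) and bottom sediment (µg/kg) across a multi-river
monitoring network.  Laboratory reporting follows the long-term method
detection limit (LT-MDL) convention: results at or above the laboratory
reporting level (LRL = 2·LT-MDL) are quantified, confirmatory detections
below the LRL are reported as *estimated*, and everything else is a
left-censored nondetect that carries no numeric value.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

WATER = "water"
SEDIMENT = "sediment"
MATRICES = (WATER, SEDIMENT)

#: concentration units per sampling matrix, fixed across a dataset
MATRIX_UNITS = {WATER: "ug/L", SEDIMENT: "ug/kg"}

QUANTIFIED = "quantified"
ESTIMATED = "estimated"
NONDETECT = "nondetect"
DETECT_STATUSES = (QUANTIFIED, ESTIMATED, NONDETECT)

CHEMICAL_CLASSES = (
    "pharmaceutical",
    "pesticide",
    "sterol",
    "hormone",
    "PAH",
    "flame retardant",
    "fragrance",
    "industrial",
    "fecal indicator",
    "alkylphenol",
    "phenolic",
    "plasticizer",
    "insect repellant",
    "other",
)

ARCHETYPES = ("urban_wwtp", "agricultural", "reference", "mixed")


class ValidationError(ValueError):
    """A record or registry violates a structural invariant."""


class SchemaError(ValueError):
    """An input file is missing required columns or metadata."""


class ConfigurationError(ValueError):
    """A benchmark, guideline, or factor table is internally inconsistent."""


@dataclass(frozen=True)
class ConcentrationRecord:
    """One analytical result for one chemical in one sample.

    ``value`` is present exactly when the result is a detection (quantified
    or estimated); left-censored nondetects carry ``value=None`` and are
    characterised only by their reporting limit.
    """

    site_id: str
    sample_id: str
    collection_date: _dt.date
    matrix: str
    chemical_id: str
    value: Optional[float]
    detect_status: str
    reporting_limit: float

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise ValidationError(
                f"unknown matrix {self.matrix!r} (expected one of {MATRICES})"
            )
        if self.detect_status not in DETECT_STATUSES:
            raise ValidationError(
                f"unknown detect_status {self.detect_status!r}"
            )
        if not self.reporting_limit > 0:
            raise ValidationError(
                f"reporting_limit must be > 0, got {self.reporting_limit}"
            )
        if self.detect_status == NONDETECT:
            if self.value is not None:
                raise ValidationError(
                    "nondetect records must not carry a numeric value"
                )
        else:
            if self.value is None:
                raise ValidationError(
                    f"{self.detect_status} records require a numeric value"
                )
            if not self.value >= 0:
                raise ValidationError(f"negative concentration {self.value}")
            if self.detect_status == ESTIMATED and not (
                self.value < self.reporting_limit
            ):
                raise ValidationError(
                    "estimated results must lie below the reporting limit "
                    f"(value={self.value}, reporting_limit={self.reporting_limit})"
                )
            if self.detect_status == QUANTIFIED and not (
                self.value >= self.reporting_limit
            ):
                raise ValidationError(
                    "quantified results must be at or above the reporting "
                    f"limit (value={self.value}, reporting_limit={self.reporting_limit})"
                )

    @property
    def detected(self) -> bool:
        return self.detect_status != NONDETECT


@dataclass(frozen=True)
class ChemicalRecord:
    """Registry entry: class membership, hydrophobicity, analytical panels.

    ``log_kow`` is the base-10 octanol–water partition coefficient; chemicals
    with low log K_ow tend to stay dissolved while hydrophobic ones sorb to
    sediment.  ``eeq_factor`` is the estrogenic potency relative to
    17β-estradiol (dimensionless); most chemicals have none.
    """

    chemical_id: str
    name: str
    chemical_class: str = "other"
    log_kow: Optional[float] = None
    analyzed_in: frozenset = frozenset(MATRICES)
    eeq_factor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.chemical_class not in CHEMICAL_CLASSES:
            raise ValidationError(
                f"unknown chemical_class {self.chemical_class!r} for "
                f"{self.chemical_id}"
            )
        bad = set(self.analyzed_in) - set(MATRICES)
        if bad:
            raise ValidationError(f"unknown matrices in analyzed_in: {bad}")
        if self.eeq_factor is not None and self.eeq_factor < 0:
            raise ConfigurationError(
                f"negative EEQ factor for {self.chemical_id}"
            )


@dataclass(frozen=True)
class SiteRecord:
    site_id: str
    river: str
    sites_order: Optional[int] = None
    archetype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.archetype is not None and self.archetype not in ARCHETYPES:
            raise ValidationError(
                f"unknown archetype {self.archetype!r} for {self.site_id}"
            )


class SiteMaxMatrix:
    """Sites × chemicals matrix of per-site maximum detected concentrations.

    The core reduced object of the analysis: one row per sampled site, one
    column per chemical, entry 0 where a chemical was never detected at the
    site.  Backed by a :class:`pandas.DataFrame`.
    """

    def __init__(self, values: pd.DataFrame, matrix: str):
        if matrix not in MATRICES:
            raise ValidationError(f"unknown matrix {matrix!r}")
        if (values.to_numpy() < 0).any():
            raise ValidationError("site maxima must be non-negative")
        self.values = values.astype(float)
        self.matrix = matrix
        self.units = MATRIX_UNITS[matrix]

    @property
    def sites(self) -> list:
        return list(self.values.index)

    @property
    def chemicals(self) -> list:
        return list(self.values.columns)

    def restrict(self, chemicals: Sequence[str]) -> "SiteMaxMatrix":
        """Restrict the column set, e.g. to a ubiquity-filtered panel."""
        missing = [c for c in chemicals if c not in self.values.columns]
        if missing:
            raise KeyError(f"chemicals absent from matrix: {missing}")
        return SiteMaxMatrix(self.values.loc[:, list(chemicals)], self.matrix)

    def __repr__(self) -> str:
        return (
            f"SiteMaxMatrix({self.matrix}, {len(self.sites)} sites x "
            f"{len(self.chemicals)} chemicals, {self.units})"
        )


@dataclass
class BenchmarkSet:
    """Water-quality benchmarks and tiered sediment quality guidelines.

    Water benchmarks are lists of (value, kind, source) per chemical with
    kind ∈ {chronic, acute}.  Sediment guidelines are (TEC, MEC, PEC)
    triples — threshold / midpoint / probable effect concentrations below,
    between, and above which adverse effects on benthic invertebrates are
    unlikely, intermediate, and probable.
    """

    water: Mapping[str, Sequence[tuple]] = field(default_factory=dict)
    sediment: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chem, entries in self.water.items():
            for value, kind, _source in entries:
                if kind not in ("chronic", "acute"):
                    raise ConfigurationError(
                        f"benchmark kind {kind!r} for {chem}"
                    )
                if not value > 0:
                    raise ConfigurationError(
                        f"non-positive benchmark {value} for {chem}"
                    )
        for chem, (tec, mec, pec) in self.sediment.items():
            if not (0 < tec <= mec <= pec):
                raise ConfigurationError(
                    f"sediment guideline for {chem} must satisfy "
                    f"0 < TEC <= MEC <= PEC, got ({tec}, {mec}, {pec})"
                )


@dataclass
class EEQTable:
    """Per-site additive estradiol-equivalent totals and contributions.

    ``contributions`` is a sites × chemicals DataFrame of partial EEQs in
    ng/L (water) or ng/kg (sediment); ``total`` is its row sum.
    """

    contributions: pd.DataFrame
    total: pd.Series
    matrix: str

    @property
    def units(self) -> str:
        return "ng/L" if self.matrix == WATER else "ng/kg"


@dataclass
class Dendrogram:
    """Agglomerative merge tree over one axis of the site-max matrix.

    ``merges`` has one row per merge: (cluster_a, cluster_b, height, size)
    where clusters 0..n-1 are leaves (in ``leaf_labels`` order) and cluster
    n+i is the product of merge i — the same encoding scipy's linkage
    matrices use.
    """

    leaf_labels: list
    merges: np.ndarray
    axis: str

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if self.merges.shape != (n - 1, 4):
            raise ValidationError(
                f"expected {n - 1} merges for {n} leaves, "
                f"got shape {self.merges.shape}"
            )

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_linkage(self) -> np.ndarray:
        """Return the merge table as a scipy-compatible linkage matrix."""
        return self.merges.astype(float)


def records_to_frame(records: Iterable[ConcentrationRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a record collection (value NaN for nondetects)."""
    rows = [
        {
            "site_id": r.site_id,
            "sample_id": r.sample_id,
            "date": r.collection_date,
            "matrix": r.matrix,
            "chemical_id": r.chemical_id,
            "value": np.nan if r.value is None else r.value,
            "detect_status": r.detect_status,
            "reporting_limit": r.reporting_limit,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "sample_id",
            "date",
            "matrix",
            "chemical_id",
            "value",
            "detect_status",
            "reporting_limit",
        ],
    )
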