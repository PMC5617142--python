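"""Reading, writing, and cross-registry validation of pipeline inputs.

All inputs are UTF-8 comma-delimited text.  The record file schema is

    site_id,sample_id,date,matrix,chemical_id,value,detect_status,reporting_limit

with an empty ``value`` field for left-censored nondetects.  Registry files
(``chemicals.csv``, ``sites.csv``, ``benchmarks_water.csv``,
``guidelines_sediment.csv``, ``eeq_factors.csv``) are documented next to
their readers below.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .model import (
    BenchmarkSet,
    ChemicalRecord,
    ConcentrationRecord,
    MATRICES,
    SchemaError,
    SiteRecord,
    ValidationError,
)

RECORD_COLUMNS = [
    "site_id",
    "sample_id",
    "date",
    "matrix",
    "chemical_id",
    "value",
    "detect_status",
    "reporting_limit",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_records(path) -> List[ConcentrationRecord]:
    """Parse a delimited record file into validated ConcentrationRecords.

    Row order is preserved.  Raises :class:`SchemaError` for missing columns
    and :class:`ValidationError` (with the offending row index) for rows
    violating record invariants.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "sample_id": str, "chemical_id": str})
    _require_columns(df, RECORD_COLUMNS, path)
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        raw_value = row.value
        value = None if pd.isna(raw_value) else float(raw_value)
        try:
            records.append(
                ConcentrationRecord(
                    site_id=str(row.site_id),
                    sample_id=str(row.sample_id),
                    collection_date=_parse_date(row.date),
                    matrix=str(row.matrix),
                    chemical_id=str(row.chemical_id),
                    value=value,
                    detect_status=str(row.detect_status),
                    reporting_limit=float(row.reporting_limit),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
    return records


def _parse_date(raw) -> _dt.date:
    if isinstance(raw, _dt.date):
        return raw
    return _dt.date.fromisoformat(str(raw))


def write_records(records: Iterable[ConcentrationRecord], path) -> None:
    rows = [
        {
            "site_id": r.site_id,
            "sample_id": r.sample_id,
            "date": r.collection_date.isoformat(),
            "matrix": r.matrix,
            "chemical_id": r.chemical_id,
            "value": "" if r.value is None else repr(r.value),
            "detect_status": r.detect_status,
            "reporting_limit": repr(r.reporting_limit),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_chemicals(path) -> Dict[str, ChemicalRecord]:
    """Read ``chemicals.csv``.

    Columns: ``chemical_id,name,chemical_class,log_kow,analyzed_in,eeq_factor``
    where ``analyzed_in`` is a ``|``-separated matrix list (empty means both)
    and ``log_kow`` / ``eeq_factor`` may be blank.
    """
    df = pd.read_csv(path, dtype={"chemical_id": str})
    _require_columns(df, ["chemical_id", "name", "chemical_class"], path)
    registry: Dict[str, ChemicalRecord] = {}
    for _, row in df.iterrows():
        cid = str(row["chemical_id"])
        if cid in registry:
            raise ValidationError(f"{path}: duplicate chemical_id {cid}")
        analyzed = row.get("analyzed_in")
        if analyzed is None or pd.isna(analyzed) or not str(analyzed).strip():
            analyzed_in = frozenset(MATRICES)
        else:
            analyzed_in = frozenset(str(analyzed).split("|"))
        registry[cid] = ChemicalRecord(
            chemical_id=cid,
            name=str(row["name"]),
            chemical_class=str(row["chemical_class"]),
            log_kow=_opt_float(row.get("log_kow")),
            analyzed_in=analyzed_in,
            eeq_factor=_opt_float(row.get("eeq_factor")),
        )
    return registry


def write_chemicals(registry: Dict[str, ChemicalRecord], path) -> None:
    rows = [
        {
            "chemical_id": c.chemical_id,
            "name": c.name,
            "chemical_class": c.chemical_class,
            "log_kow": "" if c.log_kow is None else c.log_kow,
            "analyzed_in": "|".join(sorted(c.analyzed_in)),
            "eeq_factor": "" if c.eeq_factor is None else c.eeq_factor,
        }
        for c in registry.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sites(path) -> Dict[str, SiteRecord]:
    """Read ``sites.csv`` (columns ``site_id,river[,sites_order,archetype]``)."""
    df = pd.read_csv(path, dtype={"site_id": str, "river": str})
    _require_columns(df, ["site_id", "river"], path)
    registry: Dict[str, SiteRecord] = {}
    for _, row in df.iterrows():
        sid = str(row["site_id"])
        if sid in registry:
            raise ValidationError(f"{path}: duplicate site_id {sid}")
        order = row.get("sites_order")
        archetype = row.get("archetype")
        registry[sid] = SiteRecord(
            site_id=sid,
            river=str(row["river"]),
            sites_order=None if order is None or pd.isna(order) else int(order),
            archetype=None
            if archetype is None or pd.isna(archetype)
            else str(archetype),
        )
    return registry


def write_sites(registry: Dict[str, SiteRecord], path) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "river": s.river,
            "sites_order": "" if s.sites_order is None else s.sites_order,
            "archetype": "" if s.archetype is None else s.archetype,
        }
        for s in registry.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_water_benchmarks(path) -> Dict[str, list]:
    """Read ``benchmarks_water.csv`` (``chemical_id,value,kind,source``)."""
    df = pd.read_csv(path, dtype={"chemical_id": str})
    _require_columns(df, ["chemical_id", "value", "kind"], path)
    out: Dict[str, list] = {}
    for _, row in df.iterrows():
        source = row.get("source")
        out.setdefault(str(row["chemical_id"]), []).append(
            (
                float(row["value"]),
                str(row["kind"]),
                "" if source is None or pd.isna(source) else str(source),
            )
        )
    return out


def read_sediment_guidelines(path) -> Dict[str, tuple]:
    """Read ``guidelines_sediment.csv`` (``chemical_id,tec,mec,pec[,source]``)."""
    df = pd.read_csv(path, dtype={"chemical_id": str})
    _require_columns(df, ["chemical_id", "tec", "mec", "pec"], path)
    return {
        str(row["chemical_id"]): (
            float(row["tec"]),
            float(row["mec"]),
            float(row["pec"]),
        )
        for _, row in df.iterrows()
    }


def read_benchmark_set(water_path=None, sediment_path=None) -> BenchmarkSet:
    water = read_water_benchmarks(water_path) if water_path else {}
    sediment = read_sediment_guidelines(sediment_path) if sediment_path else {}
    return BenchmarkSet(water=water, sediment=sediment)


def read_eeq_factors(path) -> Dict[str, float]:
    """Read ``eeq_factors.csv`` (``chemical_id,eeq_factor[,source]``)."""
    df = pd.read_csv(path, dtype={"chemical_id": str})
    _require_columns(df, ["chemical_id", "eeq_factor"], path)
    return {
        str(row["chemical_id"]): float(row["eeq_factor"])
        for _, row in df.iterrows()
    }


def _opt_float(raw):
    if raw is None or (np.isscalar(raw) and pd.isna(raw)):
        return None
    text = str(raw).strip()
    if not text:
        return None
    return float(text)


@dataclass
class ValidationReport:
    """Cross-registry consistency report; empty iff the dataset is consistent."""

    orphan_chemicals: List[str] = field(default_factory=list)
    orphan_sites: List[str] = field(default_factory=list)
    matrix_mismatches: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.orphan_chemicals or self.orphan_sites or self.matrix_mismatches
        )

    def summary(self) -> str:
        if self.ok:
            return "dataset consistent"
        parts = []
        if self.orphan_chemicals:
            parts.append(f"unregistered chemicals: {self.orphan_chemicals}")
        if self.orphan_sites:
            parts.append(f"unregistered sites: {self.orphan_sites}")
        if self.matrix_mismatches:
            parts.append(f"matrix/panel mismatches: {self.matrix_mismatches}")
        return "; ".join(parts)


def validate_against_registries(
    records: Iterable[ConcentrationRecord],
    chemicals: Dict[str, ChemicalRecord],
    sites: Dict[str, SiteRecord],
) -> ValidationReport:
    """Check that every record references registered chemicals/sites and
    respects each chemical's analytical panel (``analyzed_in``)."""
    orphan_chems, orphan_sites, mismatches = set(), set(), set()
    for r in records:
        chem = chemicals.get(r.chemical_id)
        if chem is None:
            orphan_chems.add(r.chemical_id)
        elif r.matrix not in chem.analyzed_in:
            mismatches.add(f"{r.chemical_id}:{r.matrix}")
        if r.site_id not in sites:
            orphan_sites.add(r.site_id)
    return ValidationReport(
        orphan_chemicals=sorted(orphan_chems),
        orphan_sites=sorted(orphan_sites),
        matrix_mismatches=sorted(mismatches),
    )
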