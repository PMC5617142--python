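"""Benchmark screening: water-quality exceedance quotients and sediment
TEC/MEC/PEC tier classification, with per-river and basin-wide summaries.

Water screening divides each site's maximum concentration by the lowest
available chronic benchmark (falling back to the lowest acute benchmark
when no chronic one exists); quotients ≥ 1 flag potential risk.  Sediment
screening classifies each site maximum against tiered sediment quality
guidelines: threshold (TEC), midpoint (MEC), and probable (PEC) effect
concentrations for benthic invertebrates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .model import (
    BenchmarkSet,
    ConfigurationError,
    SiteMaxMatrix,
    SiteRecord,
)

TIERS = ("below_TEC", "TEC", "MEC", "PEC")


def select_water_benchmark(
    chemical_id: str, benchmarks: BenchmarkSet
) -> Optional[float]:
    """Lowest chronic benchmark for the chemical, regardless of intended
    species; lowest acute benchmark if no chronic entry exists; None if the
    chemical has no benchmark at all."""
    entries = benchmarks.water.get(chemical_id)
    if not entries:
        return None
    chronic = [v for v, kind, _src in entries if kind == "chronic"]
    if chronic:
        return min(chronic)
    acute = [v for v, kind, _src in entries if kind == "acute"]
    return min(acute) if acute else None


@dataclass
class QuotientReport:
    """Exceedance quotients (site × chemical) with the benchmarks used.

    ``quotients`` holds max_conc / benchmark for benchmarked chemicals only;
    ``exceeded`` is the inclusive ``quotient >= 1`` flag; ``detected`` marks
    (site, chemical) cells with a nonzero site maximum.
    """

    quotients: pd.DataFrame
    exceeded: pd.DataFrame
    detected: pd.DataFrame
    benchmarks_used: pd.Series
    matrix: str


def exceedance_quotients(
    site_max: SiteMaxMatrix, benchmarks: BenchmarkSet
) -> QuotientReport:
    """Quotient of each site maximum against its water benchmark.

    Chemicals without a benchmark are omitted.  A site that never detected
    a chemical has quotient 0 and is not flagged.
    """
    used = {}
    for chem in site_max.chemicals:
        bench = select_water_benchmark(chem, benchmarks)
        if bench is not None:
            if bench <= 0:
                raise ConfigurationError(
                    f"non-positive benchmark {bench} for {chem}"
                )
            used[chem] = bench
    benchmarks_used = pd.Series(used, dtype=float, name="benchmark")
    sub = site_max.values.loc[:, list(used)]
    quotients = sub.div(benchmarks_used, axis=1)
    return QuotientReport(
        quotients=quotients,
        exceeded=quotients >= 1.0,
        detected=sub > 0.0,
        benchmarks_used=benchmarks_used,
        matrix=site_max.matrix,
    )


def tier_classify(concentration: float, guideline: Tuple[float, float, float]) -> str:
    """Highest sediment guideline tier the concentration meets or exceeds."""
    tec, mec, pec = guideline
    if not (0 < tec <= mec <= pec):
        raise ConfigurationError(
            f"guideline triple must satisfy 0 < TEC <= MEC <= PEC, got {guideline}"
        )
    if concentration >= pec:
        return "PEC"
    if concentration >= mec:
        return "MEC"
    if concentration >= tec:
        return "TEC"
    return "below_TEC"


def sediment_tiers(
    site_max: SiteMaxMatrix, benchmarks: BenchmarkSet
) -> pd.DataFrame:
    """Tier classification of every site maximum with a sediment guideline."""
    chems = [c for c in site_max.chemicals if c in benchmarks.sediment]
    return pd.DataFrame(
        {
            chem: site_max.values[chem].map(
                lambda v, g=benchmarks.sediment[chem]: tier_classify(v, g)
            )
            for chem in chems
        },
        index=site_max.values.index,
    )


def sediment_quotients(
    site_max: SiteMaxMatrix, benchmarks: BenchmarkSet, tier: str = "TEC"
) -> QuotientReport:
    """Exceedance quotients against one sediment guideline tier."""
    idx = {"TEC": 0, "MEC": 1, "PEC": 2}[tier]
    used = {
        chem: benchmarks.sediment[chem][idx]
        for chem in site_max.chemicals
        if chem in benchmarks.sediment
    }
    benchmarks_used = pd.Series(used, dtype=float, name="benchmark")
    sub = site_max.values.loc[:, list(used)]
    quotients = sub.div(benchmarks_used, axis=1)
    return QuotientReport(
        quotients=quotients,
        exceeded=quotients >= 1.0,
        detected=sub > 0.0,
        benchmarks_used=benchmarks_used,
        matrix=site_max.matrix,
    )


NOT_DETECTED = "--"


def summarize_by_river(
    report: QuotientReport,
    sites: Mapping[str, SiteRecord],
    denominator: str = "detected",
) -> pd.DataFrame:
    """Percent of sites per river (and basin-wide) exceeding, per chemical.

    ``denominator`` selects the base for the percentage: ``"detected"``
    (sites in the river where the chemical was detected — the convention
    that distinguishes a river with detections but no exceedances, 0%, from
    a river where the chemical was never detected, reported as ``"--"``)
    or ``"sampled"`` (all sampled sites in the river).  Values are full
    precision; round for display.
    """
    if denominator not in ("detected", "sampled"):
        raise ValueError("denominator must be 'detected' or 'sampled'")
    river_of = _river_map(report.quotients.index, sites)
    rivers = sorted(set(river_of.values))
    rows = []
    for river in rivers + ["Basin Wide"]:
        mask = (
            np.ones(len(river_of), dtype=bool)
            if river == "Basin Wide"
            else (river_of == river).to_numpy()
        )
        n_sites = int(mask.sum())
        row: Dict[str, object] = {"river": river, "n_sites": n_sites}
        for chem in report.quotients.columns:
            detected = report.detected[chem].to_numpy()[mask]
            exceeded = report.exceeded[chem].to_numpy()[mask]
            if not detected.any():
                row[chem] = NOT_DETECTED
                continue
            base = detected.sum() if denominator == "detected" else n_sites
            row[chem] = 100.0 * exceeded.sum() / base
        rows.append(row)
    return pd.DataFrame(rows).set_index("river")


def summarize_tiers_by_river(
    site_max: SiteMaxMatrix,
    benchmarks: BenchmarkSet,
    sites: Mapping[str, SiteRecord],
    denominator: str = "detected",
) -> Dict[str, pd.DataFrame]:
    """Per-tier river summaries for sediment: ``{tier: summary table}``."""
    return {
        tier: summarize_by_river(
            sediment_quotients(site_max, benchmarks, tier), sites, denominator
        )
        for tier in ("TEC", "MEC", "PEC")
    }


def site_exceedance_census(
    report: QuotientReport, sites: Mapping[str, SiteRecord]
) -> Dict[str, object]:
    """Counts of sites/rivers with at least one exceedance and the
    chemicals exceeded at least once."""
    river_of = _river_map(report.exceeded.index, sites)
    any_site = report.exceeded.any(axis=1)
    exceeding_sites = list(any_site.index[any_site])
    exceeding_rivers = sorted(set(river_of[s] for s in exceeding_sites))
    all_rivers = sorted(set(river_of.values))
    chem_any = report.exceeded.any(axis=0)
    n_sites = len(report.exceeded.index)
    return {
        "n_sites_exceeding": len(exceeding_sites),
        "percent_sites_exceeding": (
            100.0 * len(exceeding_sites) / n_sites if n_sites else 0.0
        ),
        "n_rivers_exceeding": len(exceeding_rivers),
        "percent_rivers_exceeding": (
            100.0 * len(exceeding_rivers) / len(all_rivers) if all_rivers else 0.0
        ),
        "chemicals_exceeded": sorted(chem_any.index[chem_any]),
        "n_sites": n_sites,
        "n_rivers": len(all_rivers),
    }


def _river_map(site_index, sites: Mapping[str, SiteRecord]) -> pd.Series:
    missing = [s for s in site_index if s not in sites]
    if missing:
        raise KeyError(f"sites missing from registry: {missing}")
    return pd.Series({s: sites[s].river for s in site_index}).loc[site_index]
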