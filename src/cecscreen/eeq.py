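"""Additive estradiol-equivalent (EEQ) scoring of per-site maxima.

Many trace organic contaminants are weakly estrogenic.  The EEQ collapses a
site's mixture into a single estrogenicity score by weighting each
chemical's maximum concentration by its potency relative to 17β-estradiol
and summing:

    EEQ(site) = 1000 · Σ_c  max_conc(site, c) · factor(c)

The factor of 1000 converts µg/L (water) or µg/kg (sediment) into the ng/L
or ng/kg scale on which effect levels for aquatic biota (~1–10 ng/L) are
usually quoted.  Chemicals without a published potency factor contribute
nothing.  Additivity is an assumption — concentration addition with no
synergism or antagonism.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence, Union

import pandas as pd

from .model import (
    ChemicalRecord,
    ConfigurationError,
    EEQTable,
    SiteMaxMatrix,
    SiteRecord,
)

UNIT_SCALE = 1000.0  # µg -> ng


def site_eeq(
    site_max: SiteMaxMatrix,
    chemicals: Union[Mapping[str, ChemicalRecord], Mapping[str, float]],
) -> EEQTable:
    """Total EEQ per site with per-chemical contributions.

    ``chemicals`` may be a chemical registry (factors taken from
    ``eeq_factor``, missing factors treated as non-estrogenic) or a plain
    ``chemical_id -> factor`` mapping.
    """
    factors = _extract_factors(chemicals)
    for cid, f in factors.items():
        if f < 0:
            raise ConfigurationError(f"negative EEQ factor for {cid}")
    applicable = [c for c in site_max.chemicals if c in factors]
    contributions = site_max.values.loc[:, applicable].mul(
        pd.Series({c: UNIT_SCALE * factors[c] for c in applicable}), axis=1
    )
    total = contributions.sum(axis=1)
    total.name = "total_eeq"
    return EEQTable(contributions=contributions, total=total, matrix=site_max.matrix)


def _extract_factors(chemicals) -> Dict[str, float]:
    factors: Dict[str, float] = {}
    for cid, entry in chemicals.items():
        if isinstance(entry, ChemicalRecord):
            if entry.eeq_factor is not None:
                factors[cid] = entry.eeq_factor
        elif entry is not None:
            factors[cid] = float(entry)
    return factors


def eeq_rank_report(
    eeq_table: EEQTable,
    sites: Mapping[str, SiteRecord],
    thresholds: Sequence[float] = (1.0, 10.0),
) -> pd.DataFrame:
    """Per-river listing of site EEQs, descending within river, with flags.

    A site is flagged at a threshold t when its total is strictly above t
    (``gt_1``, ``gt_10`` columns for the defaults — the conventional
    effect-level break points in ng/L).
    """
    rows = []
    for site_id, total in eeq_table.total.items():
        site = sites.get(site_id)
        rows.append(
            {
                "river": site.river if site else "",
                "site_id": site_id,
                "total_eeq": float(total),
            }
        )
    report = pd.DataFrame(rows, columns=["river", "site_id", "total_eeq"])
    for t in thresholds:
        label = f"gt_{t:g}".replace(".", "_")
        report[label] = report["total_eeq"] > t
    return report.sort_values(
        by=["river", "total_eeq", "site_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
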