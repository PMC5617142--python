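"""Data-reduction chain: censored recoding, per-chemical summaries,
ubiquity filtering, per-site maxima, and class/site totals.

The reduction philosophy is a screening one: left-censored nondetects are
recoded as zero, each site is collapsed to the maximum concentration of
each chemical observed there (maxima capture the conditions of greatest
toxicological concern and stay well-defined when most results are
censored), and the chemical panel is restricted to compounds detected in
at least a stated fraction of samples basin-wide.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .model import (
    ChemicalRecord,
    ConcentrationRecord,
    NONDETECT,
    SiteMaxMatrix,
    records_to_frame,
)

log = logging.getLogger(__name__)


def recode_censored(records: Iterable[ConcentrationRecord]) -> pd.DataFrame:
    """Numeric analysis frame with left-censored results recoded as zero.

    Quantified and estimated results keep their reported value; nondetects
    become 0.  A boolean ``detected`` column preserves censoring status
    (estimated results below the reporting limit count as detections).
    """
    frame = records_to_frame(records)
    frame["detected"] = frame["detect_status"] != NONDETECT
    frame["value"] = frame["value"].fillna(0.0)
    return frame


def chemical_summary(frame: pd.DataFrame, matrix: str) -> pd.DataFrame:
    """Per-chemical detection frequency, median, and maximum for one matrix.

    Returns a frame indexed by chemical_id with columns ``n_analyzed``,
    ``n_detected``, ``detection_frequency`` (percent), ``median`` and
    ``maximum`` (censored results enter the median and maximum as zeros),
    and ``reporting_limit`` (the modal limit, for display flagging).
    """
    sub = frame[frame["matrix"] == matrix]
    if sub.empty:
        log.warning("no records in matrix %r", matrix)
        return pd.DataFrame(
            columns=[
                "n_analyzed",
                "n_detected",
                "detection_frequency",
                "median",
                "maximum",
                "reporting_limit",
            ]
        )
    grouped = sub.groupby("chemical_id")
    out = pd.DataFrame(
        {
            "n_analyzed": grouped.size(),
            "n_detected": grouped["detected"].sum().astype(int),
            "median": grouped["value"].median(),
            "maximum": grouped["value"].max(),
            "reporting_limit": grouped["reporting_limit"].agg(
                lambda s: s.mode().iloc[0]
            ),
        }
    )
    out["detection_frequency"] = 100.0 * out["n_detected"] / out["n_analyzed"]
    return out[
        [
            "n_analyzed",
            "n_detected",
            "detection_frequency",
            "median",
            "maximum",
            "reporting_limit",
        ]
    ]


def ubiquity_filter(
    freq_table: pd.DataFrame, threshold_percent: float = 30.0
) -> List[str]:
    """Chemicals detected in at least ``threshold_percent`` of samples.

    The boundary is inclusive.  The returned panel is ordered by descending
    detection frequency, ties broken by descending maximum concentration and
    then chemical id, so panels are reproducible.
    """
    if not 0.0 <= threshold_percent <= 100.0:
        raise ValueError("threshold must lie in [0, 100]")
    keep = freq_table[freq_table["detection_frequency"] >= threshold_percent]
    keep = keep.assign(_id=keep.index.astype(str)).sort_values(
        by=["detection_frequency", "maximum", "_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return list(keep.index)


def site_maxima(
    frame: pd.DataFrame,
    matrix: str,
    sites: Optional[Sequence[str]] = None,
    chemicals: Optional[Sequence[str]] = None,
) -> SiteMaxMatrix:
    """Per-site maximum detected concentration of each chemical.

    Sites where a chemical was never detected get 0.  Every site that was
    sampled in the matrix appears as a row even if it had no detections at
    all; ``sites``/``chemicals`` extend or restrict the row/column sets.
    """
    sub = frame[frame["matrix"] == matrix]
    pivot = sub.pivot_table(
        index="site_id",
        columns="chemical_id",
        values="value",
        aggfunc="max",
        fill_value=0.0,
    )
    if sites is not None:
        pivot = pivot.reindex(index=list(sites), fill_value=0.0)
    if chemicals is not None:
        pivot = pivot.reindex(columns=list(chemicals), fill_value=0.0)
    pivot = pivot.fillna(0.0)
    pivot.index.name = "site_id"
    pivot.columns.name = "chemical_id"
    return SiteMaxMatrix(pivot.sort_index(), matrix)


def class_totals(
    site_max: SiteMaxMatrix, chemicals: Dict[str, ChemicalRecord]
) -> pd.DataFrame:
    """Per-site totals by chemical class plus the total site concentration.

    Class totals sum the per-site maxima of the class members; ``site_total``
    is the sum over all classes and equals the row sum of the site-max
    matrix exactly.
    """
    unknown = [c for c in site_max.chemicals if c not in chemicals]
    if unknown:
        raise KeyError(f"unregistered chemical(s) in site-max matrix: {unknown}")
    class_of = {c: chemicals[c].chemical_class for c in site_max.chemicals}
    totals = site_max.values.T.groupby(class_of).sum().T
    totals["site_total"] = totals.sum(axis=1)
    return totals


def matrix_overlap(
    panel_water: Sequence[str], panel_sediment: Sequence[str]
) -> Tuple[Set[str], Dict[str, int]]:
    """Chemicals frequent in both matrices, with panel-size bookkeeping.

    Returns the intersection set plus counts of each panel and of panel
    entries combined (``n_entries = n_water + n_sediment``, i.e. chemicals
    frequent in both matrices count twice).
    """
    inter = set(panel_water) & set(panel_sediment)
    counts = {
        "n_water": len(panel_water),
        "n_sediment": len(panel_sediment),
        "n_entries": len(panel_water) + len(panel_sediment),
        "n_distinct": len(set(panel_water) | set(panel_sediment)),
        "n_both": len(inter),
    }
    return inter, counts
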