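"""Presentation helpers: the per-matrix frequent-chemical summary table."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import ChemicalRecord

BELOW_RL = "<RL"


def render_summary_table(
    freq_table: pd.DataFrame,
    panel: Sequence[str],
    chemicals: Optional[Mapping[str, ChemicalRecord]] = None,
) -> pd.DataFrame:
    """Display table for a ubiquity-filtered panel, one row per chemical.

    Rows follow the panel order (descending detection frequency).  Medians
    below the chemical's reporting limit render as ``"<RL"`` — the numeric
    median of censored-as-zero data is well defined but not meaningfully
    reportable below the limit.
    """
    rows = []
    for cid in panel:
        entry = freq_table.loc[cid]
        median = entry["median"]
        rl = entry["reporting_limit"]
        chem = chemicals.get(cid) if chemicals else None
        rows.append(
            {
                "chemical_id": cid,
                "name": chem.name if chem else cid,
                "chemical_class": chem.chemical_class if chem else "",
                "log_kow": "" if chem is None or chem.log_kow is None else chem.log_kow,
                "reporting_limit": rl,
                "n": int(entry["n_analyzed"]),
                "median": BELOW_RL if pd.isna(median) or median < rl else median,
                "maximum": entry["maximum"],
                "detection_frequency": entry["detection_frequency"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chemical_id",
            "name",
            "chemical_class",
            "log_kow",
            "reporting_limit",
            "n",
            "median",
            "maximum",
            "detection_frequency",
        ],
    )
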