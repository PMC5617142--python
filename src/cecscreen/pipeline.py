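"""Pipeline orchestration: simulate/load → validate → reduce → EEQ →
benchmark screen → cluster, with persisted intermediates and a JSON run
manifest.

The pipeline is a pure function of (input files, config, seed): all
randomness flows from the single top-level seed, and a rerun with the same
inputs writes byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from . import benchmarks as bench
from . import cluster as clust
from . import datasets, io, reduction
from .eeq import eeq_rank_report, site_eeq
from .model import MATRICES, SEDIMENT, WATER
from .report import render_summary_table
from .simulate import GeneratorConfig, generate_registries, simulate_records

log = logging.getLogger(__name__)

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "threshold_percent": 30.0,
    "linkage": "complete",
    "river_denominator": "detected",
    "eeq_thresholds": [1.0, 10.0],
    "simulate": {},  # GeneratorConfig overrides; used when no input files
    "inputs": {},    # records/chemicals/sites paths for observed data
    "benchmarks": {},  # water/sediment paths; bundled tables when absent
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path) -> Dict:
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    config = {**DEFAULT_CONFIG, **user}
    for key in ("simulate", "inputs", "benchmarks"):
        config[key] = {**DEFAULT_CONFIG[key], **(user.get(key) or {})}
    return config


def _config_hash(config: Dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: Dict, out_dir, seed: Optional[int] = None) -> Dict:
    """Execute all stages, persist intermediates under ``out_dir``, and
    return the manifest (also written as ``manifest.json``)."""
    config = {**DEFAULT_CONFIG, **config}
    if seed is not None:
        config["seed"] = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "seed": config["seed"],
        "config": config,
        "config_hash": _config_hash(config),
        "row_counts": {},
        "timings_s": {},
        "outputs": [],
    }

    def _write_csv(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out / name
        df.to_csv(path, index=index)
        manifest["outputs"].append(name)
        manifest["row_counts"][name] = int(df.shape[0])

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["timings_s"][name] = round(
                    time.perf_counter() - self_inner.t0, 4
                )
                if exc is not None:
                    log.error("stage %s: failed (%s)", name, exc)
                    raise StageError(name, exc) from exc
                log.info("stage %s: done", name)

        return _Timer()

    # --- acquire records and registries -----------------------------------
    with _stage("acquire"):
        inputs = config.get("inputs") or {}
        if inputs.get("records"):
            records = io.read_records(inputs["records"])
            chemicals = io.read_chemicals(inputs["chemicals"])
            sites = io.read_sites(inputs["sites"])
        else:
            gen = GeneratorConfig(
                **{**config.get("simulate", {}), "seed": config["seed"]}
            )
            chemicals, sites = generate_registries(gen)
            records = simulate_records((chemicals, sites), gen)
            io.write_records(records, out / "records.csv")
            io.write_chemicals(chemicals, out / "chemicals.csv")
            io.write_sites(sites, out / "sites.csv")
            manifest["outputs"] += ["records.csv", "chemicals.csv", "sites.csv"]
            manifest["row_counts"]["records.csv"] = len(records)

    with _stage("validate"):
        report = io.validate_against_registries(records, chemicals, sites)
        if not report.ok:
            raise ValueError(report.summary())

    # --- reduction, EEQ, clustering per matrix ----------------------------
    frame = reduction.recode_censored(records)
    threshold = float(config["threshold_percent"])
    panels: Dict[str, list] = {}
    site_maxes = {}
    for matrix in MATRICES:
        if not (frame["matrix"] == matrix).any():
            continue
        with _stage(f"reduce[{matrix}]"):
            summary = reduction.chemical_summary(frame, matrix)
            panel = reduction.ubiquity_filter(summary, threshold)
            sampled = sorted(frame.loc[frame["matrix"] == matrix, "site_id"].unique())
            smax = reduction.site_maxima(frame, matrix, sites=sampled)
            totals = reduction.class_totals(smax, chemicals)
            panels[matrix] = panel
            site_maxes[matrix] = smax
            _write_csv(summary, f"frequency_table_{matrix}.csv")
            _write_csv(smax.values, f"site_max_{matrix}.csv")
            _write_csv(totals, f"class_totals_{matrix}.csv")
            (out / f"panel_{matrix}.txt").write_text(
                "\n".join(panel) + "\n", encoding="utf-8"
            )
            manifest["outputs"].append(f"panel_{matrix}.txt")
            manifest["row_counts"][f"panel_{matrix}.txt"] = len(panel)
            _write_csv(
                render_summary_table(summary, panel, chemicals),
                f"summary_table_{matrix}.csv",
                index=False,
            )

        with _stage(f"eeq[{matrix}]"):
            table = site_eeq(smax, chemicals)
            eeq_report = eeq_rank_report(
                table, sites, tuple(config["eeq_thresholds"])
            )
            _write_csv(eeq_report, f"eeq_{matrix}.csv", index=False)

        with _stage(f"cluster[{matrix}]"):
            panel_in_matrix = [c for c in panel if c in smax.chemicals]
            if len(panel_in_matrix) >= 2 and len(smax.sites) >= 2:
                order = clust.two_way_order(
                    smax.restrict(panel_in_matrix), config["linkage"]
                )
                clust.export_newick(
                    order.chemical_dendrogram, out / f"chemicals_{matrix}.nwk"
                )
                clust.export_newick(
                    order.site_dendrogram, out / f"sites_{matrix}.nwk"
                )
                _write_csv(order.rank_matrix, f"rank_matrix_{matrix}.csv")
                with open(out / f"order_{matrix}.json", "w", encoding="utf-8") as fh:
                    json.dump(
                        {
                            "chemical_order": order.chemical_order,
                            "site_order": order.site_order,
                        },
                        fh,
                        indent=2,
                    )
                manifest["outputs"] += [
                    f"chemicals_{matrix}.nwk",
                    f"sites_{matrix}.nwk",
                    f"order_{matrix}.json",
                ]

    # --- benchmark screening ----------------------------------------------
    bench_cfg = config.get("benchmarks") or {}
    bset = io.read_benchmark_set(
        bench_cfg.get("water"), bench_cfg.get("sediment")
    )
    if not bench_cfg.get("water") and not bench_cfg.get("sediment"):
        bset = datasets.load_survey_benchmarks()
    denominator = config["river_denominator"]
    if WATER in site_maxes and bset.water:
        with _stage("exceed[water]"):
            q = bench.exceedance_quotients(site_maxes[WATER], bset)
            _write_csv(q.quotients, "quotients_water.csv")
            _write_csv(
                bench.summarize_by_river(q, sites, denominator),
                "river_summary_water.csv",
            )
            census = bench.site_exceedance_census(q, sites)
            with open(out / "census_water.json", "w", encoding="utf-8") as fh:
                json.dump(census, fh, indent=2)
            manifest["outputs"].append("census_water.json")
    if SEDIMENT in site_maxes and bset.sediment:
        with _stage("exceed[sediment]"):
            tiers = bench.sediment_tiers(site_maxes[SEDIMENT], bset)
            _write_csv(tiers, "tiers_sediment.csv")
            for tier, summary in bench.summarize_tiers_by_river(
                site_maxes[SEDIMENT], bset, sites, denominator
            ).items():
                _write_csv(summary, f"river_summary_sediment_{tier}.csv")

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
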