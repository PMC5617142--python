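"""Seeded generator of registries and censored concentration records.

The generator emulates the statistical structure the screening pipeline
assumes, so the whole analysis runs end to end with no external data:

* a multi-river network (default 12 rivers, 3–14 sites each, 78 sites)
  where each river carries a land-use archetype — ``urban_wwtp`` rivers
  show a pharmaceutical / flame-retardant signature, ``agricultural``
  rivers a triazine/acetanilide herbicide signature, and ``reference``
  rivers are sparse;
* water sampled twice per site (spring and late summer) and sediment once;
* per-slot occurrence drawn Bernoulli with probability
  ``base_prob · archetype_multiplier · K_ow affinity`` (capped at 1), where
  the affinity term down-weights hydrophobic chemicals (log K_ow above the
  partition threshold) in water and hydrophilic ones in sediment;
* concentrations drawn lognormal — trace organics span orders of magnitude
  — with an additive archetype shift in log space;
* laboratory censoring: draws at or above the reporting limit are
  quantified; draws below it are reported as estimated with probability
  0.5 and otherwise become left-censored nondetects, a coarse stand-in for
  the rising false-negative probability of low-level results.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
from scipy import integrate
from scipy.stats import lognorm

from .model import (
    ARCHETYPES,
    ChemicalRecord,
    ConcentrationRecord,
    ESTIMATED,
    NONDETECT,
    QUANTIFIED,
    SEDIMENT,
    SiteRecord,
    WATER,
)


@dataclass(frozen=True)
class ChemicalSpec:
    """Generative parameters for one chemical.

    ``base_occurrence_prob`` is either a single probability (the K_ow
    affinity then derives per-matrix probabilities) or an explicit
    ``{matrix: prob}`` mapping for chemicals whose environmental presence
    is not governed by equilibrium partitioning (e.g. particulate-bound
    sterols, abundant in water despite log K_ow ≈ 8).

    ``lognormal_mu``/``lognormal_sigma`` parameterise the natural-log
    concentration distribution in water units (µg/L); sediment draws add
    the config-level log offset.  ``archetype_multipliers`` scale occurrence
    probability and ``archetype_log_shifts`` shift log concentration for
    sites of a given archetype.
    """

    chemical_id: str
    name: str
    chemical_class: str
    log_kow: Optional[float]
    reporting_limit: Union[float, Mapping[str, float]]
    base_occurrence_prob: Union[float, Mapping[str, float]]
    lognormal_mu: float
    lognormal_sigma: float
    archetype_multipliers: Mapping[str, float] = field(default_factory=dict)
    archetype_log_shifts: Mapping[str, float] = field(default_factory=dict)
    analyzed_in: Tuple[str, ...] = (WATER, SEDIMENT)
    eeq_factor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be > 0")
        probs = (
            self.base_occurrence_prob.values()
            if isinstance(self.base_occurrence_prob, Mapping)
            else [self.base_occurrence_prob]
        )
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError("occurrence probabilities must lie in [0, 1]")
        rls = (
            self.reporting_limit.values()
            if isinstance(self.reporting_limit, Mapping)
            else [self.reporting_limit]
        )
        for rl in rls:
            if rl <= 0:
                raise ValueError("reporting limits must be > 0")

    def rl(self, matrix: str, sediment_rl_scale: float) -> float:
        if isinstance(self.reporting_limit, Mapping):
            return float(self.reporting_limit[matrix])
        if matrix == SEDIMENT:
            return float(self.reporting_limit) * sediment_rl_scale
        return float(self.reporting_limit)

    def mu(self, matrix: str, sediment_log_offset: float) -> float:
        return self.lognormal_mu + (
            sediment_log_offset if matrix == SEDIMENT else 0.0
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale defaults: 12 rivers, 78 sites, 2 water visits per site,
    one sediment sample per site, ~27 chemicals across the major classes."""

    n_rivers: int = 12
    sites_per_river: Tuple[int, ...] = (9, 5, 3, 3, 5, 6, 14, 8, 5, 9, 5, 6)
    visits_per_site: int = 2
    archetype_assignment: Tuple[str, ...] = (
        "urban_wwtp",     # R01
        "agricultural",   # R02
        "urban_wwtp",     # R03
        "reference",      # R04
        "agricultural",   # R05
        "agricultural",   # R06
        "urban_wwtp",     # R07
        "reference",      # R08
        "agricultural",   # R09
        "urban_wwtp",     # R10
        "reference",      # R11
        "agricultural",   # R12
    )
    chemical_panel: Tuple[ChemicalSpec, ...] = ()
    kow_partition_threshold: float = 3.0
    kow_slope: float = 1.0
    sediment_log_offset: float = math.log(1000.0)
    sediment_rl_scale: float = 1000.0
    estimated_fraction_below_rl: float = 0.5
    n_chemicals: Optional[int] = None  # random-panel mode
    class_mix: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sites_per_river) != self.n_rivers:
            raise ValueError("sites_per_river must list one count per river")
        if len(self.archetype_assignment) != self.n_rivers:
            raise ValueError("archetype_assignment must cover every river")
        for a in self.archetype_assignment:
            if a not in ARCHETYPES:
                raise ValueError(f"unknown archetype {a!r}")
        if not self.chemical_panel and self.n_chemicals is None:
            object.__setattr__(
                self, "chemical_panel", tuple(default_chemical_panel())
            )

    @property
    def n_sites(self) -> int:
        return int(sum(self.sites_per_river))

    def river_ids(self) -> List[str]:
        return [f"R{i + 1:02d}" for i in range(self.n_rivers)]


def kow_affinity(
    log_kow: Optional[float], matrix: str, threshold: float, slope: float
) -> float:
    """Occurrence weight from hydrophobicity: 1 on a chemical's favored
    side of the partition threshold, decaying logistically on the other."""
    if log_kow is None:
        return 1.0
    delta = (threshold - log_kow) if matrix == WATER else (log_kow - threshold)
    return min(1.0, 2.0 / (1.0 + math.exp(-slope * delta)))


def occurrence_probability(
    spec: ChemicalSpec, archetype: str, matrix: str, config: GeneratorConfig
) -> float:
    """Effective per-slot occurrence probability, capped at 1."""
    if isinstance(spec.base_occurrence_prob, Mapping):
        base = float(spec.base_occurrence_prob.get(matrix, 0.0))
        affinity = 1.0
    else:
        base = float(spec.base_occurrence_prob)
        affinity = kow_affinity(
            spec.log_kow, matrix, config.kow_partition_threshold, config.kow_slope
        )
    mult = float(spec.archetype_multipliers.get(archetype, 1.0))
    return min(1.0, base * mult * affinity)


# ---------------------------------------------------------------------------
# default chemical panel


def _pharma(cid, name, kow, rl, mu):
    # wastewater-derived and water-centric: poor sediment recovery keeps
    # pharmaceuticals out of typical sediment panels
    return ChemicalSpec(
        chemical_id=cid,
        name=name,
        chemical_class="pharmaceutical",
        log_kow=kow,
        reporting_limit=rl,
        base_occurrence_prob={WATER: 0.45, SEDIMENT: 0.06},
        lognormal_mu=mu,
        lognormal_sigma=1.0,
        archetype_multipliers={
            "urban_wwtp": 2.2,
            "agricultural": 0.05,
            "reference": 0.02,
            "mixed": 0.9,
        },
        archetype_log_shifts={"urban_wwtp": 2.5},
    )


def _pesticide(cid, name, kow, rl, mu):
    return ChemicalSpec(
        chemical_id=cid,
        name=name,
        chemical_class="pesticide",
        log_kow=kow,
        reporting_limit=rl,
        base_occurrence_prob=0.5,
        lognormal_mu=mu,
        lognormal_sigma=1.0,
        archetype_multipliers={
            "urban_wwtp": 0.05,
            "agricultural": 2.1,
            "reference": 0.05,
            "mixed": 0.9,
        },
        archetype_log_shifts={"agricultural": 2.5},
    )


def _pah(cid, name, kow, rl, mu):
    return ChemicalSpec(
        chemical_id=cid,
        name=name,
        chemical_class="PAH",
        log_kow=kow,
        reporting_limit=rl,
        base_occurrence_prob=0.6,
        lognormal_mu=mu,
        lognormal_sigma=1.2,
        archetype_multipliers={
            "urban_wwtp": 1.8,
            "agricultural": 0.20,
            "reference": 0.10,
            "mixed": 1.0,
        },
        archetype_log_shifts={"urban_wwtp": 2.0},
    )


def default_chemical_panel() -> List[ChemicalSpec]:
    """Desk-scale panel mirroring the class mix of a basin-wide CEC survey.

    Three designed strata: an everywhere-common stratum (sterols, fecal
    indicators, an insect repellant) with explicit per-matrix probabilities
    ≥ 0.6; archetype-signature strata (urban pharmaceuticals and flame
    retardants, agricultural herbicides, urban-leaning PAHs); and a rare
    stratum (hormones, alkylphenols, an organophosphate) with probabilities
    ≤ 0.1 that should never survive a 30% ubiquity filter.
    """
    everywhere = {"urban_wwtp": 1.0, "agricultural": 1.0, "reference": 1.0, "mixed": 1.0}
    # ubiquitous chemicals occur everywhere, but minimally disturbed
    # (reference) watersheds carry systematically lower loads
    low_at_reference = {
        "urban_wwtp": 1.2,
        "agricultural": 1.0,
        "mixed": 0.8,
        "reference": -1.2,
    }
    panel = [
        # --- ubiquitous stratum (explicit per-matrix probabilities) ---
        ChemicalSpec(
            "CHOL", "cholesterol", "sterol", 7.69, {WATER: 0.2, SEDIMENT: 165.0},
            {WATER: 0.95, SEDIMENT: 0.92}, lognormal_mu=0.6, lognormal_sigma=1.0,
            archetype_multipliers=everywhere,
            archetype_log_shifts=low_at_reference,
        ),
        ChemicalSpec(
            "BSS", "beta-sitosterol", "sterol", 8.25, {WATER: 4.8, SEDIMENT: 330.0},
            {WATER: 0.75, SEDIMENT: 0.85}, lognormal_mu=2.0, lognormal_sigma=0.9,
            archetype_multipliers=everywhere,
            archetype_log_shifts=low_at_reference,
        ),
        ChemicalSpec(
            "IND", "indole", "fecal indicator", 2.14, {WATER: 0.04, SEDIMENT: 50.0},
            {WATER: 0.65, SEDIMENT: 0.95}, lognormal_mu=-2.8, lognormal_sigma=0.8,
            archetype_multipliers=everywhere,
            archetype_log_shifts=low_at_reference,
        ),
        ChemicalSpec(
            "ISO", "isophorone", "other", 1.7, {WATER: 0.05, SEDIMENT: 33.0},
            {WATER: 0.72, SEDIMENT: 0.85}, lognormal_mu=-3.0, lognormal_sigma=0.9,
            archetype_multipliers=everywhere,
            archetype_log_shifts=low_at_reference,
        ),
        ChemicalSpec(
            "DEET", "N,N-diethyl-meta-toluamide", "insect repellant", 2.18,
            {WATER: 0.04, SEDIMENT: 33.0}, {WATER: 0.68, SEDIMENT: 0.15},
            lognormal_mu=-3.0, lognormal_sigma=1.2,
            archetype_multipliers=everywhere,
            archetype_log_shifts=low_at_reference,
        ),
        # --- urban signature: pharmaceuticals + flame retardants ---
        _pharma("METF", "metformin", -0.88, 0.013, -2.0),
        _pharma("CBZ", "carbamazepine", 2.45, 0.0041, -5.0),
        _pharma("SMX", "sulfamethoxazole", 0.89, 0.0261, -4.0),
        _pharma("ATEN", "atenolol", 0.16, 0.0133, -4.2),
        _pharma("TRAM", "tramadol", 2.38, 0.0151, -3.8),
        _pharma("LID", "lidocaine", 1.44, 0.015, -4.5),
        ChemicalSpec(
            "TBEP", "tris(2-butoxyethyl) phosphate", "flame retardant", 2.75,
            0.64, {WATER: 0.5, SEDIMENT: 0.45}, lognormal_mu=0.0, lognormal_sigma=1.1,
            archetype_multipliers={
                "urban_wwtp": 2.1, "agricultural": 0.08,
                "reference": 0.04, "mixed": 0.9,
            },
            archetype_log_shifts={"urban_wwtp": 2.5},
        ),
        ChemicalSpec(
            "TDIP", "tris(dichloroisopropyl) phosphate", "flame retardant", 3.65,
            0.32, 0.5, lognormal_mu=-1.0, lognormal_sigma=1.0,
            archetype_multipliers={
                "urban_wwtp": 2.1, "agricultural": 0.08,
                "reference": 0.04, "mixed": 0.9,
            },
            archetype_log_shifts={"urban_wwtp": 2.5},
        ),
        ChemicalSpec(
            "BTZA", "methyl-1H-benzotriazole", "industrial", 1.44,
            0.141, 0.5, lognormal_mu=-1.2, lognormal_sigma=1.2,
            archetype_multipliers={
                "urban_wwtp": 1.9, "agricultural": 0.15,
                "reference": 0.08, "mixed": 1.0,
            },
            archetype_log_shifts={"urban_wwtp": 2.0},
        ),
        # --- agricultural signature ---
        _pesticide("ATZ", "atrazine", 2.61, 0.019, -3.5),
        _pesticide("METCH", "metolachlor", 3.13, 0.04, -3.8),
        _pesticide("ACET", "acetochlor", 3.03, 0.04, -4.0),
        _pesticide("METRI", "metribuzin", 1.7, 0.028, -4.2),
        _pesticide("SIM", "simazine", 2.18, 0.04, -4.0),
        # --- sediment-leaning urban: PAHs, fragrances, phenolic ---
        _pah("FLU", "fluoranthene", 5.16, 0.02, -3.0),
        _pah("PYR", "pyrene", 4.88, 0.02, -3.2),
        _pah("BAP", "benzo[a]pyrene", 6.13, 0.02, -3.8),
        _pah("PHEN", "phenanthrene", 4.46, 0.02, -3.4),
        ChemicalSpec(
            "HHCB", "hexahydrohexamethyl cyclopentabenzopyran", "fragrance", 5.9,
            0.04, 0.5, lognormal_mu=-2.0, lognormal_sigma=1.0,
            archetype_multipliers={
                "urban_wwtp": 2.0, "agricultural": 0.15,
                "reference": 0.08, "mixed": 0.9,
            },
            archetype_log_shifts={"urban_wwtp": 2.0},
        ),
        ChemicalSpec(
            "PCRES", "p-cresol", "phenolic", 1.94,
            {WATER: 0.08, SEDIMENT: 165.0}, {WATER: 0.62, SEDIMENT: 0.85},
            lognormal_mu=-1.8, lognormal_sigma=1.1,
            archetype_multipliers={
                "urban_wwtp": 1.3, "agricultural": 1.0,
                "reference": 0.2, "mixed": 1.0,
            },
            archetype_log_shifts={"urban_wwtp": 1.0},
        ),
        ChemicalSpec(
            "E1", "estrone", "hormone", 3.13, {WATER: 0.0008, SEDIMENT: 0.053},
            0.6, lognormal_mu=-6.5, lognormal_sigma=0.9,
            archetype_multipliers={
                "urban_wwtp": 1.7, "agricultural": 1.5,
                "reference": 0.1, "mixed": 1.0,
            },
            eeq_factor=0.38,
        ),
        # --- rare stratum (p <= 0.1) ---
        ChemicalSpec(
            "E2", "17-beta-estradiol", "hormone", 4.01,
            {WATER: 0.0008, SEDIMENT: 0.053}, 0.08,
            lognormal_mu=-7.0, lognormal_sigma=0.8, eeq_factor=1.0,
        ),
        ChemicalSpec(
            "NP", "4-nonylphenol", "alkylphenol", 5.76,
            {WATER: 1.6, SEDIMENT: 330.0}, 0.08,
            lognormal_mu=0.5, lognormal_sigma=1.0, eeq_factor=0.0009,
        ),
        ChemicalSpec(
            "OP", "4-tert-octylphenol", "alkylphenol", 5.28,
            {WATER: 0.32, SEDIMENT: 33.0}, 0.06,
            lognormal_mu=-1.5, lognormal_sigma=1.0, eeq_factor=0.001,
        ),
        ChemicalSpec(
            "BPA", "bisphenol A", "plasticizer", 3.32,
            {WATER: 0.8, SEDIMENT: 33.0}, 0.10,
            lognormal_mu=-1.0, lognormal_sigma=1.0, eeq_factor=0.0001,
        ),
        ChemicalSpec(
            "DCVP", "dichlorvos", "pesticide", 1.43, 0.0059, 0.05,
            lognormal_mu=-4.0, lognormal_sigma=1.0,
        ),
    ]
    return panel


def ubiquitous_subset(config: GeneratorConfig, matrix: str) -> List[str]:
    """Chemicals designed to pass a 30% ubiquity filter in the matrix:
    explicit per-matrix occurrence probability ≥ 0.6 at every archetype."""
    out = []
    for spec in config.chemical_panel:
        probs = [
            occurrence_probability(spec, a, matrix, config)
            for a in set(config.archetype_assignment)
        ]
        if min(probs) >= 0.6:
            out.append(spec.chemical_id)
    return out


def rare_subset(config: GeneratorConfig, matrix: str) -> List[str]:
    """Chemicals designed to fail a 30% ubiquity filter: occurrence ≤ 0.1
    at every archetype."""
    out = []
    for spec in config.chemical_panel:
        probs = [
            occurrence_probability(spec, a, matrix, config)
            for a in set(config.archetype_assignment)
        ]
        if max(probs) <= 0.1:
            out.append(spec.chemical_id)
    return out


# ---------------------------------------------------------------------------
# registry generation


DEFAULT_CLASS_MIX = {
    "pharmaceutical": 0.25,
    "PAH": 0.15,
    "other": 0.10,
    "sterol": 0.08,
    "pesticide": 0.08,
    "hormone": 0.08,
    "industrial": 0.06,
    "fragrance": 0.05,
    "flame retardant": 0.05,
    "fecal indicator": 0.04,
    "phenolic": 0.02,
    "alkylphenol": 0.02,
    "plasticizer": 0.01,
    "insect repellant": 0.01,
}

# class-typical log K_ow centres for randomly generated panels
_CLASS_KOW = {
    "pharmaceutical": 1.0,
    "PAH": 5.0,
    "other": 2.0,
    "sterol": 8.0,
    "pesticide": 2.8,
    "hormone": 3.5,
    "industrial": 2.5,
    "fragrance": 5.5,
    "flame retardant": 3.0,
    "fecal indicator": 2.4,
    "phenolic": 2.0,
    "alkylphenol": 5.5,
    "plasticizer": 3.5,
    "insect repellant": 2.2,
}


def _random_panel(config: GeneratorConfig, rng: np.random.Generator) -> List[ChemicalSpec]:
    mix = dict(config.class_mix or DEFAULT_CLASS_MIX)
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(classes), size=config.n_chemicals, p=probs)
    specs = []
    for i, ci in enumerate(draws):
        cls = classes[int(ci)]
        specs.append(
            ChemicalSpec(
                chemical_id=f"C{i + 1:04d}",
                name=f"synthetic {cls} {i + 1}",
                chemical_class=cls,
                log_kow=float(rng.normal(_CLASS_KOW[cls], 0.8)),
                reporting_limit=float(np.exp(rng.normal(-3.0, 1.0))),
                base_occurrence_prob=float(rng.uniform(0.05, 0.9)),
                lognormal_mu=float(rng.normal(-3.0, 1.5)),
                lognormal_sigma=1.0,
            )
        )
    return specs


def generate_registries(
    config: GeneratorConfig,
) -> Tuple[Dict[str, ChemicalRecord], Dict[str, SiteRecord]]:
    """Deterministic registries: chemicals with class/K_ow/EEQ factor and
    sites labelled with their planted river archetype."""
    rng = np.random.default_rng(config.seed)
    panel = (
        _random_panel(config, rng)
        if config.n_chemicals is not None
        else list(config.chemical_panel)
    )
    chemicals = {
        s.chemical_id: ChemicalRecord(
            chemical_id=s.chemical_id,
            name=s.name,
            chemical_class=s.chemical_class,
            log_kow=s.log_kow,
            analyzed_in=frozenset(s.analyzed_in),
            eeq_factor=s.eeq_factor,
        )
        for s in panel
    }
    sites: Dict[str, SiteRecord] = {}
    for river, count, archetype in zip(
        config.river_ids(), config.sites_per_river, config.archetype_assignment
    ):
        for i in range(count):
            sid = f"{river}-{i + 1}"
            sites[sid] = SiteRecord(
                site_id=sid, river=river, sites_order=i + 1, archetype=archetype
            )
    return chemicals, sites


def _panel_specs(config: GeneratorConfig) -> List[ChemicalSpec]:
    if config.n_chemicals is not None:
        rng = np.random.default_rng(config.seed)
        return _random_panel(config, rng)
    return list(config.chemical_panel)


# ---------------------------------------------------------------------------
# record simulation


_SPRING = _dt.date(2013, 5, 15)
_SUMMER = _dt.date(2013, 8, 20)


def simulate_records(
    registries: Tuple[Dict[str, ChemicalRecord], Dict[str, SiteRecord]],
    config: GeneratorConfig,
) -> List[ConcentrationRecord]:
    """Draw one record per (site, visit, chemical) water slot and one per
    (site, chemical) sediment slot, in a fixed deterministic order."""
    chemicals, sites = registries
    specs = [s for s in _panel_specs(config) if s.chemical_id in chemicals]
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5EC0]).generate_state(1)[0]
    )
    records: List[ConcentrationRecord] = []
    for sid in sorted(sites):
        site = sites[sid]
        archetype = site.archetype or "mixed"
        for visit in range(1, config.visits_per_site + 1):
            date = _SPRING if visit == 1 else _SUMMER
            sample_id = f"{sid}-W{visit}"
            for spec in specs:
                if WATER not in spec.analyzed_in:
                    continue
                records.append(
                    _draw(spec, sid, sample_id, date, WATER, archetype, config, rng)
                )
        sample_id = f"{sid}-SED"
        for spec in specs:
            if SEDIMENT not in spec.analyzed_in:
                continue
            records.append(
                _draw(spec, sid, sample_id, _SPRING, SEDIMENT, archetype, config, rng)
            )
    return records


def _draw(
    spec: ChemicalSpec,
    site_id: str,
    sample_id: str,
    date: _dt.date,
    matrix: str,
    archetype: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> ConcentrationRecord:
    rl = spec.rl(matrix, config.sediment_rl_scale)
    p = occurrence_probability(spec, archetype, matrix, config)
    occurs = rng.random() < p
    # the estimated-vs-censored coin is drawn unconditionally to keep the
    # random stream aligned across configs differing only in probabilities
    conc = float(
        rng.lognormal(
            mean=spec.mu(matrix, config.sediment_log_offset)
            + float(spec.archetype_log_shifts.get(archetype, 0.0)),
            sigma=spec.lognormal_sigma,
        )
    )
    coin = rng.random()
    if not occurs:
        value, status = None, NONDETECT
    elif conc >= rl:
        value, status = conc, QUANTIFIED
    elif coin < config.estimated_fraction_below_rl:
        value, status = conc, ESTIMATED
    else:
        value, status = None, NONDETECT
    return ConcentrationRecord(
        site_id=site_id,
        sample_id=sample_id,
        collection_date=date,
        matrix=matrix,
        chemical_id=spec.chemical_id,
        value=value,
        detect_status=status,
        reporting_limit=rl,
    )


def planted_truth(
    registries: Tuple[Dict[str, ChemicalRecord], Dict[str, SiteRecord]],
) -> Dict[str, Dict[str, str]]:
    """Ground-truth labels for recovery experiments."""
    chemicals, sites = registries
    return {
        "site_archetypes": {
            sid: (s.archetype or "mixed") for sid, s in sites.items()
        },
        "chemical_classes": {
            cid: c.chemical_class for cid, c in chemicals.items()
        },
    }


# ---------------------------------------------------------------------------
# analytic expectations (for Monte-Carlo validation of the pipeline)


def _recorded_cdf(
    v: float, p: float, rl: float, dist, est_frac: float
) -> float:
    """CDF of one recorded value: 0 with prob 1-p (plus the censored share
    of sub-limit draws), otherwise the lognormal draw when reportable."""
    if v < 0:
        return 0.0
    if v >= rl:
        return (1.0 - p) + p * dist.cdf(v)
    return (1.0 - p) + p * (
        est_frac * dist.cdf(v) + (1.0 - est_frac) * dist.cdf(rl)
    )


def expected_site_max(
    spec: ChemicalSpec,
    archetype: str,
    matrix: str,
    config: GeneratorConfig,
    n_samples: Optional[int] = None,
) -> float:
    """E[max of the recorded values over a site's samples], by quadrature.

    Uses E[M] = ∫ (1 − F(v)^k) dv over v ≥ 0 where F is the recorded-value
    CDF — the analytic counterpart of the simulation's occurrence,
    lognormal, and censoring steps.
    """
    k = n_samples if n_samples is not None else (
        config.visits_per_site if matrix == WATER else 1
    )
    p = occurrence_probability(spec, archetype, matrix, config)
    if p == 0.0 or k == 0:
        return 0.0
    rl = spec.rl(matrix, config.sediment_rl_scale)
    mu = spec.mu(matrix, config.sediment_log_offset) + float(
        spec.archetype_log_shifts.get(archetype, 0.0)
    )
    dist = lognorm(s=spec.lognormal_sigma, scale=math.exp(mu))
    est = config.estimated_fraction_below_rl

    def integrand(v: float) -> float:
        return 1.0 - _recorded_cdf(v, p, rl, dist, est) ** k

    upper = dist.ppf(1.0 - 1e-12)
    lo, _ = integrate.quad(integrand, 0.0, min(rl, upper), limit=200)
    hi = 0.0
    if rl < upper:
        hi, _ = integrate.quad(integrand, rl, upper, limit=200)
    return lo + hi


def expected_site_eeq(
    config: GeneratorConfig, archetype: str, matrix: str = WATER
) -> float:
    """Analytic expectation of a site's total EEQ (ng/L or ng/kg) under the
    generator: 1000 · Σ factor · E[site max]."""
    total = 0.0
    for spec in _panel_specs(config):
        if spec.eeq_factor is None or matrix not in spec.analyzed_in:
            continue
        total += 1000.0 * spec.eeq_factor * expected_site_max(
            spec, archetype, matrix, config
        )
    return total
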