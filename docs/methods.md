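# Methods

This note documents the statistical model behind `cecscreen`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Censoring model and data reduction

Laboratory results follow the long-term method detection limit (LT-MDL)
reporting convention: the laboratory reporting level is LRL = 2·LT-MDL;
results ≥ LRL are quantified, confirmatory detections below the LRL are
reported as *estimated*, and everything else is left-censored with no
numeric value. Records store only the three-state outcome and the LRL; the
LT-MDL itself is never needed downstream.

For reduction, left-censored results are recoded as **zero**. This is a
screening convention, not an estimator: with few visits per site and heavy
censoring, distribution-based imputation (Kaplan–Meier, regression on order
statistics, censored MLE) is under-determined, while zeros keep ranks,
maxima and sums well defined. Consequences worth keeping in mind:

* medians of mostly-censored chemicals are biased low — the presentation
  layer renders any median below the chemical's reporting limit as `<RL`
  rather than as a number;
* class and site totals are sums of per-site maxima over multiple samples
  and are therefore biased high relative to any single sampling occasion.

**Site maxima** are the site-level statistic throughout (not means):
screening targets the conditions of greatest toxicological concern, and
maxima remain meaningful when most observations are censored. *Estimated*
results count as detections and enter maxima, EEQ sums and ranks; they are
real confirmatory detections, merely imprecise.

Detection frequencies use per-chemical, per-matrix denominators (chemicals
are analyzed on different panels, so sample counts differ by chemical).
The **ubiquity filter** keeps chemicals detected in at least 30% of a
matrix's samples basin-wide (inclusive boundary); the threshold is a
parameter, and the returned panel is ordered by descending frequency with
deterministic tie-breaks (descending maximum, then id).

## EEQ scoring

Estradiol equivalents are additive:
`EEQ(site) = 1000 · Σ_c max_conc(site, c) · f_c`, with `f_c` the chemical's
estrogenic potency relative to 17β-estradiol and 1000 the µg→ng unit
conversion (ng/L for water, ng/kg for sediment — the scale on which
biological effect levels of roughly 1–10 ng/L are quoted, the default flag
thresholds). Concentration addition is assumed; no synergism or
antagonism. Potency factors are an **input table**, not package constants:
compilations differ by bioassay and review, so users supply their own. The
bundled `eeq_factors_synthetic.csv` is an order-of-magnitude example for
tests and demos only, and says so in its `source` column. Estimated
(below-LRL) detections are included in EEQ sums, consistent with the
detection definition above; this choice is a convention and is documented
rather than hidden.

## Benchmark screening

Water: each chemical's screening value is the **lowest chronic** benchmark
available regardless of intended species; if a chemical has no chronic
benchmark, the lowest **acute** benchmark substitutes. Quotients are
`site max / benchmark`, with the exceedance flag **inclusive** (≥ 1).
Sediment: concentrations are classified against TEC ≤ MEC ≤ PEC guideline
triples; the assigned tier is the highest guideline met or exceeded
(boundaries inclusive), so tier is non-decreasing in concentration by
construction.

River summaries report the percent of sites exceeding per chemical. The
denominator is **detection-conditioned** by default — sites in the river
where the chemical was detected — which distinguishes "detected but never
exceeding" (0%) from "never detected" (rendered `--`). An
all-sampled-sites denominator is available as an option; published survey
tables are not always explicit about this choice, so both are first-class.
Percentages are kept at full precision internally and rounded only for
display.

## Co-occurrence clustering

Concentrations span orders of magnitude across chemicals, so each
chemical's site maxima are replaced by **ranks across sites** (average
ranks for ties; the sites where a chemical was never detected all carry
the tied lowest rank rather than being dropped, keeping site vectors
complete). Ranks absorb any strictly monotone per-chemical transform,
which the test suite asserts as an invariance property. Chemicals with a
constant column are retained (with a warning); dropping them would change
the site geometry silently.

Both axes are clustered agglomeratively on Euclidean distances between
rank vectors. **Complete linkage** is the default (the common default of
the R hierarchical-clustering family used for published CEC heatmaps);
average and single linkage are options. The agglomeration is implemented
in the package rather than delegated because rank data produce *exactly*
tied distances, and reproducible dendrograms require a defined tie rule:
among minimum-distance pairs, the pair whose sorted leaf-label tuples
compare lexicographically smallest merges first. Merge tables use the
scipy linkage encoding. Correctness is checked two ways: against a naive
O(n³) re-scan oracle (exact equality of heights and partition sequences on
1,000 random ≤ 8-leaf instances) and against scipy's linkage heights on
tie-free data.

Display order comes from recursive traversal with the tighter (lower
merge height) subtree first, ties by label; a singleton leaf counts as
height 0 and therefore precedes any merged subtree. Cutting at *k*
clusters applies the first *n − k* merges (equivalently, truncates the
merge forest below the (n−k+1)-th merge height); labels are numbered by
first-leaf appearance. Newick export assigns each child a branch length
of parent height − child height.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, at desk scale:

* **Network**: 12 rivers, 78 sites (3–14 per river), water sampled twice
  per site (spring, late summer), sediment once — mirroring a basin-wide
  survey footprint of ~156 water and 78 sediment samples.
* **Archetypes**: each river is urban/WWTP-influenced, agricultural, or
  reference (a `mixed` label exists for user configs). Defaults place
  ~45% of sites on urban rivers, ~35% agricultural, ~20% reference.
* **Occurrence**: per sample slot, Bernoulli with probability
  `base_prob · archetype multiplier · K_ow affinity`, capped at 1. The
  affinity term is 1 on a chemical's favored side of the log K_ow = 3
  partition threshold and decays logistically (unit slope) on the other
  side — hydrophilic chemicals favor water, hydrophobic ones sediment.
  Chemicals whose presence is not equilibrium-driven (particulate-bound
  sterols, fecal indicators) carry explicit per-matrix probabilities that
  bypass the affinity term.
* **Concentrations**: lognormal, because trace-organic surveys span
  orders of magnitude (the bundled survey's water maxima run from 0.0284
  to 72.2 µg/L); the survey asserts no distribution, so this is a
  generator assumption. Archetype effects add a shift in log space
  (≈ 2–2.5 σ for signature classes). Sediment draws add log(1000) to µg/L
  parameters, and scalar reporting limits scale ×1000 into µg/kg.
* **Censoring**: draws at or above the reporting limit are quantified;
  draws below it are *estimated* with probability 0.5, otherwise
  nondetect. The coin is a deliberate simplification of the real
  false-negative gradient (which rises as concentration falls toward the
  LT-MDL); the exact gradient is not modeled.
* **Planted structure**: the default 29-chemical panel has three designed
  strata — an everywhere-common stratum (occurrence ≥ 0.6 at every
  archetype; sterols, fecal indicators, isophorone, DEET), archetype
  signatures (urban: 6 pharmaceuticals, 2 organophosphate flame
  retardants, a benzotriazole, urban-shifted PAHs and a fragrance;
  agricultural: 5 herbicides; reference rivers additionally carry a −1.2
  log shift on the common stratum, reflecting low human and livestock
  loads), and a rare stratum (occurrence ≤ 0.1: estradiol, alkylphenols,
  bisphenol A, dichlorvos) that must never survive the 30% filter.

Calibration guarantees, all asserted by the suite and recomputed by the
acceptance script:

* designed-ubiquitous chemicals always pass the 30% filter and designed-
  rare ones never do, in both matrices;
* detection counts match exact binomial 99% intervals when censoring is
  inert;
* reconstructed mean site EEQ matches a closed-form expectation within
  Monte-Carlo error (< 10% relative at 1,000+ sites). The expectation
  integrates `E[max of k recorded values] = ∫ (1 − F(v)^k) dv` by
  quadrature, where `F` is the recorded-value CDF combining occurrence,
  the lognormal draw, and the estimated/censored coin;
* cutting the site dendrogram at k = number of planted archetypes recovers
  the labels with median adjusted Rand index ≥ 0.9 over 20 seeds, in both
  matrices.

What the generator does **not** emulate: hydrological transport and
dilution, temporal autocorrelation between visits, spatial correlation
along a reach, laboratory QC structure (spikes/blanks/recoveries), or
correlated occurrence beyond the shared archetype effect. Passing the
recovery tests therefore shows the pipeline is correct and well calibrated
under the assumed structure — not that real tributary data will cluster
this cleanly.

## Numerical and interface conventions

* Units are fixed per matrix (µg/L water, µg/kg sediment) across a file;
  mixed units are rejected at the registry level rather than converted.
* Dates are informational; spring and late-summer visits are pooled before
  maxima (no seasonal stratification).
* One record per environmental sample is assumed; QC replicates should be
  excluded upstream.
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; simulation iterates sites, visits and
  chemicals in a fixed sorted order, so outputs are byte-reproducible
  across runs and platforms.
* The full pipeline writes a JSON manifest (config echo, config hash,
  seed, package version, per-artifact row counts, stage timings); reruns
  with identical inputs are byte-identical apart from the manifest's
  timing fields.
* Problem sizes used by the test suite and acceptance script — 78-site
  networks, 20 recovery seeds, 1,000 oracle instances at ≤ 8 leaves,
  800–2,000-site EEQ calibration runs — were chosen to make each
  statistical check decisive at interactive runtimes.

## Known limitations

* No censored-data estimators beyond the zero convention; median summaries
  below the reporting limit are qualitative (`<RL`).
* Exceedance screening is per chemical; no mixture toxicity, species
  sensitivity distributions, or probabilistic risk characterization.
* Cluster leaf orders depend on the linkage and tie conventions described
  above; other implementations (e.g. R's `hclust` inside `heatmap.2`) may
  produce different but equally valid orders on tied rank data.
* The bundled EEQ factor table is synthetic; real analyses must supply a
  vetted potency compilation.
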