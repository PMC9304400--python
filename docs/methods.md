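# Methods

This note documents the models and procedures the package implements, the
design choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## The roster filter

A species enters the analyzable large-carnivore roster when four rules all
hold: (1) it is not in a configured exclusively-herbivorous family; (2) its
body mass meets the threshold for its taxon/system class — sharks and rays,
marine teleosts and marine mammals 50 kg, freshwater teleosts 20 kg,
reptiles and amphibians 10 kg, birds 1 kg, terrestrial mammals 12 kg; (3) a
shark, ray or bony fish has mean trophic position ≥ 4.0; (4) a mammal has
≥ 50% carnivory. Choices:

* **Thresholds are inclusive (≥) uniformly**, exposed as a config switch.
  Source descriptions mix "above" (mass) with "or greater" (trophic
  position); a single convention keeps the audit rules predictable, and the
  boundary species affected are enumerable through the switch.
* **Fishes with no trophic estimate are excluded** (reason
  `missing_trophic`) rather than imputed; likewise mammals with no diet
  datum (`missing_diet`). Imputation from external trait databases is out
  of scope; conservative exclusion keeps the audit honest.
* **A fish flagged both marine and freshwater takes the lower (20 kg)
  threshold**, so diadromous borderline species are not falsely excluded.
* The herbivorous-family list is configuration, not code: no authoritative
  list ships with the package.

Data-Deficient and Not-Evaluated species are removed (with a reported
count) before any status-based analysis.

## Genuine status-change metrics

Categories are ranked LC=0, NT=1, VU=2, EN=3, CR=4, EW=5, EX=6; DD and NE
are unranked. EW and EX receive ranks so change magnitudes involving them
are well defined, although ordinary cohorts rarely exercise them. For each
consecutive assessment pair whose later event is flagged *genuine* and
falls on or after the taxon baseline (terrestrial and marine mammals 1996,
birds 1988, reptiles and amphibians 1980, all others 1996 — configurable),
the signed step is rank(previous) − rank(current): positive means risk
decreased (VU→LC = +2). Pairs touching an unranked category are skipped
with a warning. A genuine change assessed *before* the baseline is dropped
entirely, not truncated. The classification (improved / declined /
unchanged) is the sign of the cumulative step sum; `recovery` is
improvement OR an increasing listed trend. A species with unknown trend
counts as neither increasing nor decreasing (merged into the negative
class); callers who prefer to drop unknown-trend species from denominators
can filter beforehand, and the prevalence analyses use known-trend species
only.

Percent threatened T/K over K known-status species is bracketed by
Data-Deficient bounds 100·T/(K+D) and 100·(T+D)/(K+D): all D Data-Deficient
species assumed safe, or all assumed threatened.

## Threat and action coding

Raw threat codes are recoded to 23 analyst categories (fishing, bycatch,
hunting, conflict, ecosystem modification, hydrological changes, energy,
species introductions, fire, aquaculture, transportation, and so on)
through an editable mapping table; unmapped codes are reported, never
silently dropped. Each threat-by-species observation is scored
timing + scope + severity with defaults ongoing 3 / past 1 / future 1 /
unknown 2; whole 3 / majority 2 / minority 1 / unknown 2; very rapid 3 /
rapid 2 / slow-but-significant 1 / negligible or none 0 / unknown 1. A
score ≤ 5 is *low*, ≥ 8 *high*. Association designs exclude low-impact
threats and future-timed threats by default; both switches toggle
independently for sensitivity comparison. The scoring maps are fully
configurable because assessment practice varies; the defaults follow
published Red List impact-scoring guidance.

Actions are binary per-species indicators under two schemes: the 11 IUCN
"Conservation Actions In-Place" categories and 15 analyst-defined actions
nested in 5 broader groups (legislation, exploitation management, habitat,
species-level interventions, social). Duplicate flags collapse to 1 with a
warning.

## Statistical engine

* **Logistic regression** is fitted by IRLS (`statsmodels` GLM, binomial
  family), tolerance 1e-8, max 100 iterations. Wald intervals are reported
  at both 90% and 95%. Profile intervals are out of scope. Quasi-complete
  separation (a fitted probability within 1e-6 of 0/1 alongside a
  coefficient beyond ±10) sets `separation_flag` and is *reported, not
  penalized*: unstable intervals are shown as such rather than silently
  regularized, matching how the underlying analyses present them.
* **Backwards-AIC selection** greedily removes the single term whose
  removal most decreases AIC, stopping when no removal strictly decreases
  it; candidates are scanned in sorted-name order so ties break
  deterministically. On well-separated designs with ≤ 6 predictors this
  greedy path attains the exhaustive best-subset optimum (verified in
  tests); that is a property of the data regime, not a guarantee.
* **Forward/backward LRT selection** alternates entry (smallest
  likelihood-ratio p ≤ 0.05) and removal (largest p > 0.10) until no move
  qualifies. A single noise predictor is falsely entered with probability
  ≈ the entry level; AIC selection by contrast retains a noise predictor
  with asymptotic probability P(χ²₁ > 2) ≈ 0.157, which is inherent to the
  AIC penalty, not an implementation artifact.
* **Goodness-of-fit**: Pearson X² against expected proportions; asymptotic
  χ² p unless any expected count < 5, in which case the p-value is
  simulated under the multinomial null with the add-one estimator
  (1 + #{X²_sim ≥ X²_obs})/(n_sim + 1), default n_sim = 10,000, explicit
  seed required. Constant-zero expected categories must be dropped by the
  caller (the orchestrator does).
* **Post-hoc binomial tests** per category use the exact two-sided
  minimum-likelihood rule (the doubled-tail rule is available by flag,
  since sidedness conventions differ between implementations), adjusted by
  Holm step-down — the standard referent of "sequential Bonferroni".
* **Fisher's exact test**: 2×2 by full hypergeometric enumeration
  (minimum-likelihood two-sided rule); larger tables by Monte Carlo over
  Patefield-sampled tables with the observed margins, counting tables whose
  conditional probability does not exceed the observed one.
* **Kruskal–Wallis** is tie-corrected with a χ² reference (df = k−1); the
  all-identical degenerate case returns H = 0, p = 1. **Dunn's post-hoc**
  z-statistics use pooled mean ranks with the Σ(t³−t)/(12(N−1)) tie
  correction and Holm adjustment.
* No procedure touches global random state; every Monte Carlo routine takes
  an explicit seed.

## Prevalence analyses and orchestration

Null baselines (trend shares and change-in-status shares per taxon and
globally) are an input artifact, representing an external multi-year
Red List compilation; they are never computed from live data. Defaults are
global increasing/decreasing/stable = 0.07/0.38/0.55 and
improved/declined/unchanged = 0.02/0.07/0.91, values of the order seen in
decade-scale Red List summaries. Four analyses — trend × taxon, trend ×
realm, change × taxon, change × realm — each produce per-group GOF results
with post-hocs (when significant at 0.05) plus one independence test;
multiplicity is handled within each analysis (Holm over its post-hocs), not
across analyses. Realm membership means any positive range proportion, so a
species can appear in several realms.

The action models are fitted per response (improved; increasing; either) as
three separate binary regressions rather than one joint model. Sensitivity
reruns (marine mammals excluded for actions; scavengers excluded for
threats) operate on copies — the primary cohort is never mutated — and each
fit records its exclusion set. Constant (all-0/all-1) design columns are
dropped before selection with a log note. Written outputs use fixed column
order, fixed float formatting and sorted JSON keys, and provenance is the
seed plus a config digest — deliberately no timestamps — so identical
config + seed yields byte-identical files.

## The synthetic-data generator

The generator emulates the statistical structure the association analyses
assume, with defaults set to the study conditions: 362 candidate species; a
taxon mix spanning the six vertebrate groups; ~8% Data Deficient with
known-status shares of roughly half Least Concern and ~38% threatened;
action and threat prevalences anchored to reported per-category species
counts (fishing ~35% of species, bycatch ~34%, conflict ~8%, fire ~2.5%,
aquaculture ~2.2%); and trait distributions sitting mostly, not entirely,
above the filter thresholds so the roster filter has real work.

Outcomes are drawn from independent logistic models given the species'
action/threat flags — this is the minimal structure under which the
downstream regressions are correctly specified and recoverable:

* improvement: intercept −5.5 plus log-odds log 6.8 (international
  legislation, IUCN scheme), log 3.0 (harvest management plan) and
  ½·log 13 (national legislation, analyst scheme). The intercept is
  calibrated so the *marginal* improvement rate is ≈ 3.4%, the reported
  prevalence of genuine improvements;
* increasing trend: intercept −3.0 with effects log 2.3 (international
  legislation) and log 2.0 (conservation sites identified), giving < 10%
  increasing overall;
* decreasing trend: intercept −0.9 with threat effects log 7.4 (conflict)
  and log 4.5 (hydrological changes);
* status decline: intercept −3.2 with threat effects log 5.6 (ecosystem
  modification) and log 4.0 (hydrological changes). This model is an
  extension beyond the improvement/trend structure so that the `declined`
  response also has recoverable generating coefficients.

Assessment histories are then *constructed to realize the drawn outcome
exactly*: an improved species carries a genuine positive cumulative change
(1–2 steps) dated after its taxon baseline; a declined species a genuine
negative change; a neutral species only non-genuine changes (30% of the
time) or a constant history. A separate generic backward random walk
(`generate_history`) with configurable step distribution and
genuine-labeling probability exists for exercising the trajectory engine
independently of the outcome models.

Randomness is one root seed split into named substreams (traits, status,
actions, threats, outcomes, histories, ranges, realms), so adding a later
stage never perturbs earlier draws; a fixed seed gives byte-identical
cohorts. Ranges are rectangular blocks (≤ half the grid side by default) on
an abstract 50×50 grid, with placements recorded so exact per-cell richness
is available in closed form as ground truth.

**What the generator does not emulate — and hence what passing tests do not
show about real data:**

* No phylogenetic or spatial autocorrelation; species are exchangeable
  given their flags. Real Red List data are strongly clustered in both.
* Current status is drawn independently of threats and actions, so the
  `threatened` response has no planted association structure (the
  `declined` and `decreasing` responses do). A real cohort's
  threat–status association reflects history the generator does not model.
* Two mechanical constraints mildly misspecify the outcome models at the
  margins: a species drawn "declined" but currently Least Concern cannot
  realize a decline (no lower rank exists) and is recorded as not declined;
  a Data-Deficient species cannot realize an improvement. Parameter-recovery
  checks therefore use the unconstrained improved/decreasing responses.
* Action and threat flags are mutually independent; real conservation
  actions are allocated in response to threats and risk.

## Problem sizes and numerical tolerances used in testing

The test suite checks closed-form logistic solutions to 1e-6; stepwise
selection against exhaustive best-subset search on 20 cohorts of n = 300
with 6 predictors; 95% Wald coverage and null-predictor exclusion on 50
cohorts of n = 2000 with planted log-odds 0/1/2; Monte Carlo GOF type-I
calibration over 2000 replicates of a multinomial(100; 0.03, 0.47, 0.5)
null at n_sim = 10,000 against the exact binomial 99% band; a 30-case
hand-derived trajectory battery; richness against brute-force overlays on
50×50 grids; and byte-identical outputs of two full runs at n = 2000.
These sizes were chosen to make sampling error small relative to the
assertions while keeping the default suite quick to run.

## Known limitations

* No ordinal (proportional-odds) regression of three-level responses; the
  binary compressions are the supported path.
* No aggregate Red List Index; the per-species cumulative-change metric is
  related but not the RLI.
* The range module is grid-agnostic but ships no projections, area
  weighting, or real elevation/realm rasters; real 5-km rasters can be
  substituted by supplying explicit cell sets and a labeled realm grid.
* The coastal overlap rule — marine realm labels suppressed where realm
  types would overlap — is realized by construction in the single-label
  realm map and is an assumption, not a validated treatment.
* Baseline null distributions ship as plausible defaults and should be
  replaced with a real compilation for substantive use.
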