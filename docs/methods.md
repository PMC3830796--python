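# Methods

## Preprocessing model

The unit of analysis is a prescription paired with the outcome observed at
the next visit.  Visits are ordered per patient by `visit_index`; gaps in
the index are treated as consecutive encounters (inter-visit time is not
modelled).  The symptom score is the sum of per-symptom severities on the
4-point scale; the number of symptoms is configurable (default 15) and the
score is scale-agnostic.  The symptom change value `SCV = (prev − next) /
prev` is undefined when the previous score is zero; such pairs are removed
as missing rather than given an arbitrary value, matching the exclusion of
missing values in the source cohort design.  The 30% effectiveness
threshold is inclusive (`SCV ≥ 0.30 → outcome 1`).  An exact ratio of 0.30
computed from integer scores compares equal to the 0.30 literal in IEEE
arithmetic, so no tolerance is applied.  Herb names are matched exactly
after whitespace trimming; no synonym resolution is attempted.

The record-count identity `records + missing + multi-visit patients =
total visits of multi-visit patients` is asserted by property tests on
random cohorts.

## Coreness and effectiveness

Coverage, average confidence `α`, support `S_α` and patient-based support
follow the definitions in the README.  The group split assigns a record to
the candidate's group when its coverage reaches the configured level; the
garbled published membership inequality is read this way, the only reading
consistent with `S_α` and the worked support example.

Two standardisations of the effective-proportion difference coexist by
design:

* **EV (optimisation score)** uses the *pooled* standard error
  `sqrt(p̂(1−p̂)(1/n₁+1/n₀))` with `p̂` the pooled effective proportion.
  The source defines EV only as a difference over a "joint standard
  deviation"; the pooled form is the natural joint estimate and is stable
  as a search signal.
* **The reported Z-test** uses the *unpooled* (Wald) standard error
  `sqrt(p₁(1−p₁)/n₁ + p₀(1−p₀)/n₀)` with a two-sided normal P and no
  continuity correction, because this variant reproduces every published
  P value (0.002/0.004/0.009/0.013/0.014) to three decimals under the
  count reconstruction `n₁ = round(S₁·419)`, `k = round(EP·n)`; the pooled
  variant does not.  Both are available behind a `pooled` flag.

The Wald form is anti-conservative at small group sizes: at `n₁ = 20,
n₀ = 400` its type-I error is ≈ 0.07–0.08 across null proportions, while
the pooled form calibrates to ≈ 0.05.  The calibration test therefore
exercises the pooled variant; the inflation of the unpooled variant is
asserted explicitly in a companion test.  `−log` is base 10 (forced by the
1.301 ↔ 0.05 correspondence); `p = 0` is capped at 16 with a warning.

Empty groups make EV undefined; during GA search such candidates take the
penalty sentinel `−R` so they are never selected, and in reporting they
raise a named error.

## Genetic algorithm

Chromosomes are binary vectors over the herb vocabulary.  Defaults mirror
the published configuration (population 1000, 200 generations, crossover
probability 0.7, tournament size 15, initial gene probability
`k·N_set/m` with `k = 1`, penalty `R = 200`, `N_set = 8`, level-1 support
floor 2%); every value is a config key and `m` generalises the study's
hard-coded 230-herb space.

Operator choices where the source is ambiguous:

* **Crossover**: "multipoint" is implemented with a configurable number of
  cut points (default 2, the smallest multipoint variant), drawn without
  replacement from the internal boundaries; per-locus the children carry
  exactly the parents' gene multiset.
* **Mutation**: the "three-way swap" is read as a cyclic 3-permutation of
  three distinct gene values, which preserves the herb count.  A per-gene
  bit-flip (default rate 1/m) is provided as an alternative because the
  swap operator cannot change the herb count, which freezes the population
  size profile once selection collapses diversity.
* **Selection** is tournament with replacement and uniform random
  tie-breaking; replacement is generational with an optional elite block
  (`n_elite` individuals retained, default 1 when enabled).
* Duplicate removal in the returned candidate list is by exact chromosome
  equality; the list contains every final-generation chromosome with
  positive fitness, sorted by fitness.

Fitness evaluation is vectorised: record-coverage-at-level is the integer
comparison `|CEF ∩ x| ≥ ceil(level·N)` computed via one float32 matrix
product (exact for these magnitudes), from which supports and group
proportions follow by column reductions.  One population evaluation at
n ≈ 450 records, m = 230, population 1000 takes a few milliseconds, so a
full search runs in seconds on one CPU.

### Search behaviour and the recovery experiment

The level-1 fitness landscape is deceptive on realistic cohorts: the
highest-EV infeasible candidates are tiny all-positive coverage groups,
and growing a candidate toward the minimum herb count is locally
fitness-decreasing, so a single run with the default operators converges
to a dead end with appreciable probability.  The planted-formula recovery
experiment therefore runs the search at confidence level 0.8 — inside the
stated `α ≥ 0.7` operating range of the method, where partial coverage
makes the surface smooth — with bit-flip mutation (rate 2/m), tournament
size 8, crossover probability 0.3, elitism on, and up to three independent
restarts per seed, mirroring the multi-execution protocol used in the
source parameter study.  Recovered candidates are compared to the planted
set by Jaccard similarity.  Problem sizes used in the automated
experiments: population 1000 × 300 generations per restart on a
150-patient cohort; the tiny-vocabulary oracle check uses population 200 ×
60 generations against exhaustive enumeration of all 2¹² − 1 subsets.

## Synergy analysis

Pair strata (both herbs, first-without-second, second-without-first) are
exact record scans; a pair with an empty stratum is excluded.  The
permutation test shuffles the outcome vector across all records with
prescriptions fixed (2000 permutations by default), recomputes SI per
permutation, and reports the one-sided add-one-smoothed
`p = (1 + #{SI* ≥ SI}) / (B + 1)`; permutations with an undefined SI are
redrawn, so the null conditions on SI being defined.  One-sidedness
follows the stated hypothesis of interest (SI > 1); smoothing avoids
`p = 0`.  Permutation across patients (rather than within) is the
default; the longitudinal correlation this ignores is a known limitation.

## Synthetic cohorts

The generator emulates the cohort shape the method was developed on:

* 150 patients; visits per patient `1 + Poisson(3)` truncated to [1, 9]
  (mean ≈ 3.9, matching the reported "near 4");
* prescription sizes `9 + Binomial(27, 14/27)` (range 9–36, mean 23);
* herb popularity Zipf–Mandelbrot `w_j ∝ 1/(j+6)`, calibrated once so the
  most popular herb appears in ≈ ⅔ of prescriptions (matching the top
  reported herb frequency, 395 of 586 records);
* per-herb retention probability 0.8 between a patient's consecutive
  visits (`persistence`), reflecting incremental adaptation of a running
  prescription; an optional template layer (`n_templates` shared base
  formulas, default off) adds cross-patient co-occurrence structure;
* baseline effective proportion 0.22.

Outcomes are attached by trajectory inversion: an effectiveness flag is
drawn per consecutive-visit pair (elevated probability when the
prescription fully contains a planted formula), and the next visit's
symptom total is sampled so SCV crosses the 30% threshold exactly when the
flag is set.  Effective steps occasionally clear all symptoms
(`p_remission = 0.03`), which makes the following pair missing — the
mechanism that produces the small missing-value fraction seen in real
preprocessing.  Totals are decomposed uniformly into per-symptom scores of
at most 3.

What passing tests on these cohorts do **not** show: real prescriptions
are more strongly clustered around clinical templates than the default
popularity model, symptom dynamics are not modelled (outcomes are assigned,
not emergent), and dosage is absent entirely.  Recovery results quantify
the search's behaviour under the generator's assumptions, not clinical
performance.

## Numerical and degenerate-input conventions

* Coverage/level comparisons are exact integer threshold tests, never
  float divisions, inside the GA; the metrics module uses float64 ratios
  whose exact-equality cases (e.g. 7/10 vs 0.7) round to identical
  doubles.
* Empty analysis tables, empty groups, zero standard errors, undefined
  SI and p = 0 all raise named errors or are flagged and counted, never
  silently imputed.
* All randomness flows through `numpy.random.Generator` objects seeded
  explicitly; identical seed + config + data reproduces every output
  bit-for-bit, and the pipeline manifest records the seed and a
  configuration hash (output paths excluded).

## Known limitations

* The LOPO report excludes holdouts that empty a group (they are counted
  and flagged); with very concentrated formulae the summary can rest on
  few defined holdouts.
* The permutation and Z-tests treat records as exchangeable across
  patients; within-patient correlation is only addressed by PBS and LOPO,
  not by the test statistics themselves.
* The GA provides no convergence guarantee; the restart protocol bounds
  but does not eliminate the probability of missing the global optimum.
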