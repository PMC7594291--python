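# Methods

`deerseed` implements a mechanistic model of endozoochorous (gut-mediated)
long-distance seed dispersal (LDD) by individual red deer, together with
the inference pipeline that quantifies (Q1) how LDD probability varies
between individuals and months, (Q2) how seed load varies on the same
axes, (Q3) whether the two covary across individuals, (Q4) whether the
covariation differs between plant species, and (Q5) whether species'
seed-load-weighted LDD potential deviates from a random-association null.

## The dispersal model

The per-seed dispersal distance is the product of vector displacement and
gut passage time, d = v·p, realized on empirical movement data rather than
on a parametric velocity distribution:

1. **Passage time p.** The retention model is a table of excretion
   probabilities over 14 time intervals (upper bounds 1, 3, 6, 9, 12, 15,
   18, 21, 24, 30, 36, 42, 48, 54 h after ingestion), one probability
   vector per (feeding-trial, plant-species) cell. Simulation draws an
   interval from the cell's probabilities and places the time uniformly
   within it; the first interval spans [0, 1 h). All cells are pooled with
   equal weight (100,000 draws per cell at full scale: 6 × 6 × 100,000 =
   3,600,000 values) into one empirical distribution of p used for all
   plants downstream. Uniform-within-interval placement is an assumption —
   the retention model supplies only interval masses — and is the
   maximum-entropy choice; it is visible in the code as the only
   within-interval law.

2. **Displacement.** For each individual, endpoints (candidate seed
   deposition sites) are drawn uniformly with replacement from the GPS
   fixes themselves — not from interpolated positions — carrying their
   timestamps. For each endpoint a passage time p is drawn from the pooled
   distribution; the ingestion start point is located on the trajectory at
   (endpoint time − p), linearly interpolated in easting, northing and
   elevation between the bracketing fixes (`start_rule: nearest` snaps to
   the nearest fix instead, to measure sensitivity to this choice).
   Horizontal displacement is the planar Euclidean distance start→end;
   vertical displacement is the signed elevation difference.

3. **Left-censoring.** A start time falling before the first fix triggers
   a redraw of the whole (endpoint, p) pair, up to `max_redraws` (default
   100) rounds; still-unresolved events are dropped and the dropped
   fraction is always reported. On season-long hourly trajectories the
   dropped fraction is ~0%.

4. **LDD probability.** Per (individual, calendar month of the endpoint)
   cell: the fraction of events strictly beyond 1000 m horizontally, and
   beyond +50 m / below −50 m vertically. Thresholds are absolute, not
   quantile-based, and strict (`d > threshold`). The draw budget is per
   individual (100,000 at full scale), stratified post hoc by endpoint
   month, so cell sample sizes are proportional to time tracked per month.

## Seed load Q

Pellet groups are measured by volume; dry mass = volume × 0.13 g/ml.
A sample's load for a species is seedlings ÷ dry mass (seedlings per
gram). Note the underlying field protocol phrases this as "divided by the
volume, multiplied by 0.13 g/ml", which taken literally yields
seedlings·g/ml²; the dimensionally consistent per-gram form is the
default, and `q_rule: literal` reproduces the literal arithmetic for
auditing. A species absent from a sample contributes q = 0; the
(individual, month) cell value is the mean over that cell's samples
(`cell_aggregation: sum | pooled` are alternatives; the aggregator is not
fixed by the protocol). Species found in ≥ 3 distinct greenhouse control
trays are excluded as substrate contaminants before any load is computed.
Per-species analyses are restricted to species dispersed by ≥ 5 distinct
individuals.

## Inference

- **Q1/Q2 (variance partitioning).** Separate one-way OLS fits per factor,
  reported alongside the two-factor additive fit (with sequential sums of
  squares in both orders, since the design can be unbalanced). LDD
  probability is partitioned at the cell grain (21 × 8 = 168 cells);
  log-transformed total seed load at the sample grain (~504 samples),
  matching the degrees of freedom of the original analyses. Raw
  probabilities are used as the ANOVA response.
- **Q3 (regression).** One point per individual: log total seed load
  (averaged over sampled months) against logit LDD probability (pooled
  over the individual's events), both z-standardized; simple OLS with the
  F test on 1 and n−2 df.
- **Q4 (interaction).** Full model `log q ~ species * logit(LDD)` vs the
  additive reduction, F-tested on the interaction, with the interaction's
  partial R² = (SSR_reduced − SSR_full)/SSR_reduced.
- **Transforms.** Exact 0/1 probabilities are smoothed as
  (p·(n−1) + 0.5)/n with n the cell's event count before the logit (finite
  draws can produce exact zeros); zeros in loads add half the smallest
  positive value before the log. "Scaled" is read as z-standardization.
  No multiple-testing correction is applied in Q1–Q4.
- **Q5 (LDD potential).** A species' potential per orientation is
  Σ q_c·LDD_c / Σ q_c over the sampled cells. The null permutes the
  species' load vector uniformly across all sampled cells (zero-load cells
  included; `permutation_support: positive` restricts to positive cells)
  and takes the 2.5/97.5 percentiles of 100,000 permutations (full
  enumeration replaces sampling on toys with ≤ 7 cells). Observed
  potentials strictly outside the interval are deviations; ties count as
  non-deviations. The across-species test is the upper-tail probability of
  the deviation count under Binomial(n_tests, 0.05).

OLS fits are delegated to statsmodels; the package's own arithmetic is
checked against explicit sum-of-squares oracles in the test suite.

## The synthetic study

The original GPS data are confidential, so the package ships a generator
reproducing the study design: 21 reproductively mature females, hourly
fixes May–December, three dung samples per individual per month (mean
volume 172.3 ml), and a plant community observed as ~62 species.

- **Movement** is a correlated random walk with exponential step lengths
  (individual mean `step_scale`, drawn log-normally with median 220 m/h
  and log-sd 0.5 across individuals), von Mises turning angles
  (concentration 1.0), and a linear per-step pull of 0.3 toward an
  individual home-range centre. Because the pull is linear, the walk is an
  AR(1) process in position and is simulated by a linear filter with no
  per-step Python loop. These values were fixed so the pooled synthetic
  kernel sits in the regime of the original study (mean horizontal
  displacement ≈ 0.6–0.7 km, ≈ 20% of events beyond 1 km, 99% quantile a
  few km).
- **Terrain** is an analytic sum of two incommensurate sinusoids (200 m
  relief over a 4 km wavelength); elevation is a pure function of
  position, which gives exact oracles for vertical displacement. Vertical
  1%/99% displacement quantiles land near ±230 m, the order of the
  original ±280 m.
- **Seed loads.** Species mean seedling counts per sample follow a
  piecewise-geometric rank-abundance curve (5.0 down to 0.015 across the
  first 19 ranks, a sharp drop, then a slow tail to 0.004) chosen so that
  roughly 19–22 of 62 species are dispersed by ≥ 5 individuals while
  nearly the whole community appears at least once per season. Each
  species has a Gaussian month profile (peak month spread over the season,
  sd 1.5 months). Expected counts multiply the base rate, the month
  profile, a mean-one log-normal individual effect (log-sd 0.5), an
  optional log-linear mobility term exp(coupling × standardized mobility),
  and a mean-one log-normal per-sample overdispersion (log-sd 1.0);
  realized counts are Poisson. The variance defaults reproduce the
  original load partition (individual ≈ 23%, month ≈ 5%, joint ≈ 28% of
  log-load variance at the sample grain). `mobility_coupling` defaults to
  0 (no load–mobility association); positive values implement the
  alternative world in which seed load concentrates on mobile deer.
- **Contaminants.** Three weedy species are planted in ≥ 3 control trays
  each (plus one borderline species in exactly 2 trays, which must survive
  the filter), exercising the exclusion rule end to end.
- **Determinism.** Every generator seeds a `SeedSequence` from its spec;
  identical specs give bit-identical outputs, and the pipeline fans one
  master seed into independent per-stage streams.

What the generator does **not** emulate: habitat selection, landscape
barriers, seasonal home-range shifts, fix dropout and irregular sampling,
collar error, germination failure differing between individuals, and
phylogenetic structure in the community. Passing tests therefore show that
the pipeline recovers the structure this generator puts in — not that the
original field estimates are correct.

## Numerical choices and degenerate inputs

- Duplicate GPS timestamps collapse to the first occurrence (logged);
  animals with < 2 usable fixes are excluded with a warning.
- Passage probability vectors must sum to 1 within 1e-6 (renormalized) —
  larger deviations are an error naming the cell.
- Quantiles are type-7 (linear interpolation) throughout.
- Degenerate permutation nulls (fewer than 2 distinct load values)
  collapse the interval to the observed value and are flagged; all-zero
  load species are skipped with a warning.
- An interaction fit with zero residual variance reports an infinite F
  and p = 0.

## Simulation sizes

Full-study settings (100,000 endpoint draws per individual, 100,000
passage draws per cell, 100,000 permutations) are the config defaults.
The shipped test suite and `scripts/acceptance.py` run the same pipeline
at reduced sizes (2,000–20,000 draws, 1,000–5,000 permutations), chosen so
Monte-Carlo error stays well inside every tolerance asserted; all sizes
are plain config values.

## Known limitations

- **The permutation null is mildly anticonservative on clustered loads.**
  Loads of one species are correlated across months within an individual
  (shared individual effects), and LDD probability is strongly
  individual-structured, while the null treats all cells as exchangeable.
  Under zero coupling the realized deviation rate per species × orientation
  test is ≈ 6% rather than the nominal 5% (and ≈ 8% for the horizontal
  orientation alone, where between-individual LDD variance is largest).
  Coverage simulations quantifying this are part of the test suite.
- **Deviations are correlated across species.** All species share one LDD
  table and correlated load patterns, so the binomial across-species test
  assumes an independence that does not hold; single datasets can show
  deviation counts far from the nominal rate in either direction. The
  meta-test is reported exactly as defined, with this caveat.
- The pooled passage distribution ignores plant-species identity; species
  differences in retention are out of scope by design.
- Start-point interpolation between hourly fixes understates path
  tortuosity; the `nearest` rule bounds the effect of this choice.
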