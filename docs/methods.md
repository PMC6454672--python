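# Methods

## Scope and model

The package analyses a screening cohort of middle-aged (40–59) adults, free
of stroke at baseline, with eight binary questionnaire risk factors and a
4-year first-ever-stroke outcome (cerebral infarction, cerebral hemorrhage
or TIA). The estimand is the conditional incidence P(stroke | factor
combination) for every combination of one, two or three factors (8 + 28 +
56 = 92 combinations), and from it the incidence ratio to the no-factor
baseline used to derive preliminary-screening criteria.

The causal structure is assumed, not learned: stroke is taken to be
directly caused by the risk factors, so each combination's network is a
star DAG with one edge per factor into the stroke node. Under
maximum-likelihood parameter learning on discrete data the stroke node's
CPT entry for a parent configuration is the empirical conditional
frequency, so inference reduces to filter-and-count; the package keeps this
reduction explicit and tests it against a brute-force oracle. No
general-purpose inference engine is needed for this topology, and no
Dirichlet smoothing is applied — zero-support and zero-event cells are
reported as such, with distinct flags, rather than smoothed away.

### Conditioning semantics

"The incidence with hypertension and smoking" is ambiguous: it may
condition only on the named factors being positive (others free) or on the
full 8-factor configuration (others negative). Both are implemented
(`marginal` and `exact` semantics); `marginal` is the default, matching the
per-combination network reading, and every output records which was used.
Exact-semantics support never exceeds marginal support for the same
factors, and produces many more empty cells.

## Cleaning

Order of exclusions (fixed and reported per stage): prior stroke at
baseline → Dixon outlier centers → data-error records → lost-to-follow-up
records. Loss to follow-up makes the outcome unknowable, so those records
cannot enter any conditional frequency.

The Dixon screen works on the per-center positive rates of the four
lab-confirmed factors (hypertension, diabetes, atrial fibrillation,
dyslipidemia), grouped by the 7 districts × urban/rural (14 groups), rates
sorted ascending. The two-index ratios are

    r_high = (x_n − x_{n−2}) / (x_n − x_3)   — tests the maximum x_n
    r_low  = (x_3 − x_1) / (x_{n−2} − x_1)   — tests the minimum x_1

the standard r22 statistics, robust against two further outliers on either
flank. Semantics follow the standard convention: the statistic built from
x_n tests (and removes) x_n, the one built from x_1 removes x_1. Both
extremes are tested each pass; if both exceed the critical value, the
larger statistic wins the pass. Removal repeats on the shortened series
until nothing exceeds the critical value. A zero denominator (no spread
among the inner order statistics) defines the statistic as 0. All four
factor screens run on the same input snapshot (the post-prior-stroke
cohort), and a center flagged for *any* factor is excluded (union rule).

Critical values: two-tailed α = 0.05 r22 values for n = 8…30, embedded in
`cleaning.DIXON_R22_CRITICAL`. They were calibrated by seeded Monte Carlo
(5×10⁶ Gaussian-null replicates per n, 95th percentile of
max(r_high, r_low); `scripts/calibrate_dixon_table.py` regenerates them),
which reproduces the classic printed Dixon/Rorabacher tables at their
3-decimal precision — the same procedure validated against the universally
reproduced r10 column first. Groups with fewer than 8 centers are skipped
(logged), since the statistics are undefined below 6 and untabulated below
8; consequently at most n − 7 centers can ever be removed from a series.
No multiplicity correction is applied across the 14 × 4 series. At these
settings roughly 4–5% of outlier-free series lose a center (the iterative
re-testing and the skewness of binomial rates for rare factors such as
atrial fibrillation inflate the nominal 5% slightly in opposite
directions); an injected center whose rate is 3× its group is removed
essentially always at realistic center sizes (~300 people).

## Incidence estimation and uncertainty

Point estimate: events/support on the full cleaned cohort. Uncertainty:
the inference is repeated `n_iterations = 10,000` times, each on a random
subsample of `fraction = 0.8` of the cohort drawn without replacement, and
summarised by

* `resample_mean` — mean of the iteration values;
* `ci90` — mean ± 1.645 · sd(iterations)/√n_iterations, a standard-error-
  of-the-mean interval. This is the headline interval because it matches
  the character of the reported intervals this analysis style produces
  (widths of ~10⁻⁵ at 10⁴ iterations); it quantifies Monte-Carlo
  uncertainty of the subsampling mean, **not** sampling uncertainty of the
  cohort;
* `percentile90` — the empirical 5th–95th percentile interval of the
  iteration values, the statistically conventional subsampling interval,
  always reported alongside.

With fraction f, the percentile interval's half-width is ≈
1.645·σ·√(1/f − 1) where σ is the binomial SE of the full-cohort estimate,
so at f = 0.8 it is about half a true 90% CI and **under-covers** the
generator truth (~59%); at f = 0.5 (delete-half subsampling) the two
coincide and coverage is the nominal 90%, which is what the coverage test
verifies. Users wanting calibrated percentile intervals should set
`fraction=0.5` or `method="bootstrap"` (with replacement).

Execution: an iteration's value depends on the subsample only through the
number of matched-conditioning records k and events e among them, whose
exact joint subsampling distribution is nested hypergeometric
(k ~ Hypergeom(n, support, m); e | k ~ Hypergeom(support, events, k)). The
default path draws (k, e) directly — distributionally identical to
materialising the subsample, O(1) per iteration — making 10⁴ iterations ×
92 patterns essentially free; `method="subsample"` keeps the literal path
and a test checks the two agree. Iterations with k = 0 are excluded from
the summaries; a pattern unsupported in more than half the iterations is
flagged `low_support`. All randomness flows from a single integer seed.

## Criteria derivation

Ratios are plain quotients p/baseline (the "X times higher" readings all
match this, not (p−baseline)/baseline). Machine output keeps raw ratios;
display rounds half-up to the printed precision. Zero-incidence
combinations never qualify at any threshold.

Median convention: the table's C(8,k) values *including explicit zeros* are
sorted ascending and the upper-middle element (1-based position n/2 + 1)
taken for even n. This is the only convention consistent with both
reference-table medians (0.0226 of 56 triples, 0.0117 of 28 pairs); the
average-of-middle-two convention reproduces neither, and is therefore not
offered.

"Newly added" criteria: the screening program's existing rule already
covers every ≥3-factor combination, and a `reference_threshold` marks the
pair combinations already proposed at a stricter ratio; no single factor is
in any prior criteria set. Hence `newly_added_pairs` are the pairs with
threshold ≤ ratio < reference, while `newly_added_singles` are all
qualifying singles. At threshold 2.5 vs reference 3 this yields four pairs
and two singles (hypertension, ratio 3.1, and atrial fibrillation, 2.9);
defining singles symmetrically against the reference threshold would
exclude hypertension, contradicting the analysis this reproduces.

## Synthetic cohort: what it emulates, and what it does not

The generator emulates the structure the analysis relies on: 14 district ×
urbanicity groups with `centers_per_group` = 10 centers each; eight factors
with configurable prevalences and optional pairwise association; a
configurable outcome model; independent prior-stroke (3%),
lost-to-follow-up (1.81%) and data-error (0.5%) flags; injectable outlier
centers (per-center factor-rate multipliers); a multinomial stroke-subtype
mix 0.503/0.091/0.406 (infarction/hemorrhage/TIA). Default size 48,007
matches the cleaned analysis cohort; defaults for prevalences
(hypertension 0.25, AF 0.01, smoking 0.25, dyslipidemia 0.30, diabetes
0.08, lack of exercise 0.20, overweight 0.25, family history 0.05) and
logistic log-odds increments (1.15, 1.10, 0.10, 0.25, 0.85, 0.60, 0.55,
0.50 over a logit(0.0070) intercept) are plausible for a Chinese
middle-aged screening population and give combination incidences on the
order 0.006–0.2 over the 0.0070 baseline, with rare combinations
(anything involving AF plus another uncommon factor) yielding the
zero-event cells the real tables show.

Factor dependence uses a sequential conditional-Bernoulli scheme in
canonical factor order: factor j's conditional log-odds is a calibrated
base plus pairwise association terms θᵢⱼ for already-drawn factors, with
the base solved (Brent root-finding on the exactly enumerated prefix
distribution) so configured marginal prevalences hold exactly at any θ.
Default θ = 0 (independence). The scheme's 2⁸ joint distribution is
enumerable in closed form, which is what makes
`true_conditional_incidence` an exact oracle — the decisive advantage over
a Gaussian-copula scheme, whose orthant probabilities would themselves
need numerical approximation.

Not emulated: age- or sex-dependent risk (the analysis uses neither),
intervention effects of the screening program itself on subsequent
incidence, informative loss to follow-up, center-level clustering of
outcome risk, and seasonal/temporal structure. Passing recovery tests
therefore show the estimator is correct *for this data-generating
mechanism*, not that the mechanism captures every feature of a real
screening cohort — in particular, real zero cells may reflect intervention
or reporting artefacts the generator does not produce.

## Problem sizes and numerical choices

Parameter recovery is checked on 200,000-record cohorts (every supported
pattern's MLE within 3 binomial SEs of the exact truth; note the normal
approximation is marginal for cells with expected events < 1, which the
default conditions keep rare), false-removal rates on 224 simulated series,
CI coverage on 200 replicates of 8,000 records at fraction 0.5, and
subsampling reproducibility at 50,000 records × 10,000 iterations. Ties in
result tables are broken by canonical factor order (the questionnaire's
listing); result tables sort by descending incidence within each k.
Floating-point ties in Dixon statistics favour the high side.

## Known limitations

* The Dixon critical-value table covers n = 8…30 centers per group;
  larger groups need the table extended (the calibration script does so
  directly).
* The SE-of-mean `ci90` shrinks with iterations and should not be read as
  cohort-level uncertainty; use `percentile90` at `fraction=0.5` or the
  bootstrap for that.
* Exact-semantics estimates on 48k-person cohorts are extremely sparse for
  triples; marginal semantics is the meaningful default at this scale.
* The iterative Dixon screen's false-removal rate is mildly above the
  nominal α for rare factors (binomial skewness); a variance-stabilising
  transform of rates was considered and rejected to keep the procedure as
  the analysis defines it.
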