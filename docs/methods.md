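# Methods

## Model

Disease progression is a discrete-time Markov chain on four states: CN
(cognitively normal), MCI (mild cognitive impairment), AD (Alzheimer's
disease) and Withdrawal.  Allowed transitions are CN ⇄ MCI, MCI → AD and
every clinical state → Withdrawal; Withdrawal is absorbing and AD can only
exit to Withdrawal.  CN → AD in a single assessment interval and AD → MCI
reversal are excluded from the structure: both are observed at low rates
in longitudinal cohorts and are interpreted as diagnostic
misclassification, so the counting code tallies them in a separate report
rather than in the transition counts.

The chain is *time-homogeneous within one-year intervals*: transition
probabilities are estimated independently per interval and assumed
constant inside it.  No covariates act on the probabilities; every source
of between-individual heterogeneity is collapsed into the per-edge
sampling distributions described next.

## Parameters

Each of the six free (off-diagonal) edges carries an average one-year
transition probability modelled as an independent Normal(mean, sd) on the
probability scale.  The packaged default table (`admarkov/data/
default_transition_params.csv`) holds the values fitted to the ADNI-1/GO/2
longitudinal cohort:

| edge | mean | sd |
|---|---|---|
| CN→MCI | 0.0432 | 0.0055 |
| CN→Withdrawal | 0.0372 | 0.0046 |
| MCI→CN | 0.0218 | 0.0044 |
| MCI→AD | 0.0954 | 0.0090 |
| MCI→Withdrawal | 0.0528 | 0.0057 |
| AD→Withdrawal | 0.1765 | 0.0127 |

Self-transition probabilities are never drawn or stored as parameters;
they are always the closure 1 − Σ(off-diagonal row), which guarantees
row-stochasticity by construction.  The published self-transition fits are
kept in `REPORTED_SELF_TRANSITION_MEANS` for cross-checking: MCI (0.8300)
and AD (0.8235) equal their closures exactly, while the reported CN value
(0.9197) differs from the closure 0.9196 by one unit in the last printed
digit — a rounding artefact in the source table, which is why the package
treats closures, not the reported diagonals, as authoritative.

Draws from the per-edge Normals are truncated (clipped) to [0, 1]; if a
row's off-diagonal draws sum above 1 the whole row is redrawn.  With the
default parameters rejection is vanishingly rare, so the marginal shape
near the mean is essentially untouched.  Whether out-of-range draws should
be clipped or resampled is a genuinely open design point; clipping was
chosen because it is simple, vectorises, and its effect is negligible at
the default SDs (≈8 standard deviations from the nearest bound).

## Estimation pipeline

1. **Filtering.**  Subjects whose baseline diagnosis is SMC ("significant
   memory concern", a baseline-only category) are excluded, then subjects
   with only a screening visit.  A subject matching both rules is
   attributed to the SMC rule.  When the cohort table carries a
   `withdrew` flag, a single-visit subject whose flag is set is retained:
   that subject is a documented first-interval withdrawal, and dropping
   them was found (during parameter-recovery testing) to bias withdrawal
   probabilities low by roughly 15%.
2. **Counting.**  Visits within ±3 months of a scheduled yearly
   assessment snap to it (the window is configurable).  Each consecutive
   pair of observed yearly assessments contributes one transition.  A
   visit gap (seen at years 1 and 3 but not 2) contributes nothing for
   the spanned intervals — the two-year jump is not decomposable without
   an interpolation model, and none is assumed.  Withdrawal is counted in
   the interval after the last visit, unconditionally when no `withdrew`
   column exists (then end-of-study censoring is indistinguishable from
   withdrawal), and only where flagged when it does.
3. **Interval MLE and pooling.**  The interval estimate is the observed
   transition fraction.  The *average* one-year probability pools counts
   across intervals before taking the ratio — a sample-size-weighted
   average of interval estimates, which is the MLE under within-interval
   homogeneity.  Origins with zero observations yield NaN flags, never
   silent zeros.
4. **Bootstrap and Normal fit.**  B = 10⁴ replicates by default.  Each
   replicate resamples the transition multiset with replacement within
   every (interval, origin) stratum at its original size — implemented as
   a multinomial draw over the observed destination fractions, which is
   distributionally identical and vectorises.  The Normal fit per edge is
   the maximum-likelihood one: sample mean and divisor-B standard
   deviation.

## Synthetic cohorts

The generator emulates the structure of a staggered multi-protocol
observational study: enrolment waves with caps of 10/7/5 years of
follow-up (fractions 50/25/25%), yearly assessments, a baseline mix of
30% CN / 47% MCI / 17% AD / 6% SMC loosely matching a memory-clinic
recruitment profile, per-state withdrawal, and trajectories generated as
Markov walks from a known ground-truth table.  One seed drives a
counter-based per-subject substream, so any subject's trajectory is
reproducible independently of cohort size.

What it deliberately does **not** emulate: diagnostic misclassification
(generated trajectories contain no forbidden transitions), covariates
(age, APOE ε4, education), biomarker trajectories, irregular visit
timing, or selection bias in recruitment.  Passing recovery tests
therefore demonstrates the correctness of the estimation machinery under
the model's own assumptions, not robustness to the violations real cohort
data exhibit.

A fixed deterministic 1737-subject fixture (106 baseline-SMC, 7
screening-only, 1624 analysable) exercises the baseline filters.

## Trial simulator

Defaults: N = 1000 individuals, 120 months, monthly steps, R = 10⁴
realisations, all-CN initial composition.  Per realisation each
individual receives one annual probability draw (constant over time
unless treated), and all individuals update synchronously each step.

* **Time-scale conversion.**  Annual probabilities are assigned but the
  chain steps monthly; the conversion is the per-edge complement-root
  q = 1 − (1 − p)^(1/12), with self-loops re-closed.  It is exact for
  single-exit rows (monthly survival compounds to the annual self-loop),
  monotone in p, and a per-edge approximation for competing exits; a
  matrix 12th-root alternative would be exact but can produce negative
  entries and is not implemented.  `steps_per_year` is configurable, so
  annual-step simulation (no conversion at all) is available for
  validation.
* **Treatment.**  Efficacy E multiplies the annual probability of a
  treated progression edge by 1 − E; the freed mass returns to the
  origin's self-loop.  Effects are homogeneous across individuals.  The
  activation delay uses a single semantics covering both "late
  administration" and "slow onset": transitions starting at or after
  `delay_months` use the treated matrix, earlier ones the untreated one.
* **Denominator.**  Reported state proportions are relative to the
  enrolled N; withdrawn individuals stay in the denominator, counted in
  the Withdrawal state, so the AD proportion remains a probability over
  the enrolled cohort.
* **Summaries.**  Per time point: mean, SD (divisor R−1) and the
  equal-tailed 95% credible interval of the realisation distribution.
  Quantiles use the empirical order-statistic (inverted-CDF) convention,
  so a two-point distribution yields the exact extremes rather than
  interpolated values.
* **Secondary endpoints** (computed online when `track_individuals` is
  set, so full trajectories are never stored): AD incidence proportion
  (ever-AD / N), person-months per state counted at the start of each
  step (with all rates zero the baseline state accumulates exactly the
  trial duration), probability of reaching a target state within the
  horizon, and mean first-passage month among reachers.
* **RNG.**  One master seed; realisation r uses the substream
  `SeedSequence([seed, r])`, so increasing R extends rather than reshuffles
  results.  Within a realisation, per-individual draws are vectorised in a
  fixed order.

## Comparison statistics

The treatment effect at a time point is the mean difference of AD
proportions (untreated − treated).  Significance uses the pooled-variance
two-tailed z test for equality of two binomial proportions, without
continuity correction — the standard choice at trial sizes around N =
1000.  A pooled proportion of exactly 0 or 1 makes the statistic
undefined; such comparisons are flagged degenerate with p = 1 (the
conservative direction).  Because a whole distribution of counts is
available, two usage modes exist and are labelled distinctly: the test
applied once to expected counts (mean proportion × N, rounded
half-away-from-zero), and the per-realisation rejection rate, which is
the Monte-Carlo power of the design (or its size under the null).  The
per-individual probability draws add variance beyond binomial, but at the
default SDs the extra term is ≈0.4% of the binomial variance, so the
test's calibration survives (verified by the null-calibration test).

## Problem sizes in tests and the acceptance script

Monte-Carlo checks run at R = 2000 realisations (the matrix-power
equivalence check at N = 1000 × R = 2000 × 120 months; ordering checks at
a 5-year horizon), parameter recovery at 5000 subjects with B = 10⁴
bootstrap replicates, and null calibration over 1000 simulated trial
pairs at N = 500 — sizes chosen so the whole suite completes in a few
minutes while keeping Monte-Carlo standard errors an order of magnitude
below the effects being asserted.  Statistical assertions use 3-standard-
error tolerances against independent oracles (matrix-power forecasts,
absorbing-chain first-passage arithmetic, closed-form binomial moments,
scalar root-finding, and statsmodels' z test).

## Known limitations

* Transition probabilities carry no covariate effects; extending the
  chain with per-stratum tables is the natural next step.
* The per-edge monthly conversion is approximate for rows with competing
  exits (error O(p²), well below sampling noise at the default rates).
* The Normal model for probabilities is unbounded in principle; clipping
  handles the tails but a Beta model would be more natural at larger SDs.
* Estimates from cohorts without a withdrawal flag conflate loss to
  follow-up with administrative censoring, inflating withdrawal
  probabilities when follow-up is capped.
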