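# Methods

## Two-stage design model

A single-arm trial observes Bernoulli(p) responses.  Stage 1 enrolls
`n1` subjects and stops for futility iff responses `X1 <= r1`; otherwise
stage 2 adds `n - n1` subjects and efficacy is declared iff the total
`S > r`.  There is no early efficacy stop: the stage-1 boundary is
futility-only, matching the monitored trial's rule.  All operating
characteristics are exact binomial sums:

* `PET(p) = P(X1 <= r1)` (binomial CDF),
* `reject(p) = Σ_{x1 > r1} P(X1 = x1) · P(X2 > r − x1)`,
* `E[N](p) = n1 + (1 − PET(p)) · (n − n1)`.

**Boundary convention.** Efficacy requires `S >= r + 1`.  Software
conventions differ here; a protocol phrased as "six or more of 21" is
`r = 5` in this package.

**Design search.** `search_simon` enumerates every `(n1, n, r1, r)` with
`n <= n_max` (default 100, which covers practical phase 2 designs at
negligible cost), keeping designs with `reject(p0) <= alpha` and
`reject(p1) >= 1 − beta`.  For each `(n1, r1)` only the smallest feasible
`r` is kept (larger `r` only loses power).  The restricted distribution
of `S` given continuation is a convolution of the truncated stage-1 pmf
with the stage-2 pmf, and hopeless `r1` values are pruned via the bound
`power <= P(X1 > r1; p1)`.  Minimax minimizes `n`, ties broken by smaller
`E[N](p0)` (the standard convention); optimal minimizes `E[N](p0)`.

## Exact inference under the attained design

The trial treated 22 patients against 21 planned; stage 2 therefore
attained `n2 = 7`.  All post-trial inference conditions on the attained
design `(r1, n1, n2)` — this is what reproduces the published adjusted
rates, and the package treats the attained `n2` as data, making no
assumption about whether over-enrollment was prospective.

**UMVUE (Jung–Kim).**  For a trial that continued, with total responses
`s`,

    p̂ = Σ_j C(n1−1, j−1) C(n2, s−j) / Σ_j C(n1, j) C(n2, s−j),

`j` over `max(r1+1, s−n2) .. min(n1, s)`, evaluated in exact rational
arithmetic (`fractions.Fraction` over `math.comb`); a stage-1 stop
reduces to `x1/n1`.  Unbiasedness over the full outcome space is
verified by enumeration in the test suite.

**Stagewise ordering.**  Outcomes are ordered with every completed trial
above every stage-1 stop; completed trials by total `s`, stops by `x1`.
The one-sided p-value against `p0` is the upper tail of this ordering at
the observed outcome:

    p = Σ_{j>r1} P(X1=j; n1, p0) · P(X2 >= s−j; n2, p0),

with the stage-2 tail equal to 1 when `s − j <= 0`.  For a stage-1 stop
the tail collapses to `P(X1 >= x1; n1, p0)`; such trials never reject
(this branch is an extension beyond what the monitored trial needed).

**Confidence intervals.**  Two conventions are implemented because they
serve different purposes and no single interval does both jobs:

* `method="koyama-chen"` (default): invert the single upper-tail
  function at `(1−level)/2` and `1−(1−level)/2`.  This is the convention
  of published adjusted intervals for Simon-type designs and is exact on
  the rejection side (the side the p-value reports), but its two-sided
  coverage can dip below nominal at response probabilities far above the
  estimate — enumeration at this trial's design shows coverage down to
  ~0.70 near p = 0.95.
* `method="equal-tail"`: lower bound from the upper tail, upper bound
  from the lower tail (stage-1 stops plus completed totals `<= s`), each
  at `(1−level)/2`.  Enumeration over the full outcome space confirms
  coverage `>= level` everywhere on a 0.05-step grid; the price is a
  wider upper bound.

Both tails are monotone in p; bounds are found by bracketing bisection
(`brentq`) to 1e−6 on p, with degenerate tails mapped to 0 or 1.

**Other estimators.**  Clopper–Pearson intervals come from the beta
quantile form (via statsmodels), with the `x=0` / `x=n` endpoints pinned
to 0 and 1.  Odds ratios use the Wald CI on the log scale; the
Haldane–Anscombe rule adds 0.5 to every cell when any cell is zero.  A
zero-cell table corrected this way reproduces a published point estimate
(≈23.6) but not its CI, which evidently came from a differently
penalized logistic fit; the package does not guess at that remedy and
the reconstructed table is marked derived/unverified in the fixtures.

## Toxicity monitoring

A beta-binomial rule: prior `Beta(a, b)` (default uniform `Beta(1,1)`),
posterior `Beta(a+x, b+n−x)`, pause for review when
`P(p_tox > p_unacceptable | data) > cutoff`.  The unacceptable rate and
cutoff have no defaults: the source protocol does not print them, so the
module is deliberately parameter-explicit.  The boundary is advisory
(pause-and-evaluate), not a binding stop, and `stopping_boundary`
tabulates, per interim size, the smallest toxicity count that triggers
review.

## Survival analysis

Kaplan–Meier fitting and the log-rank statistic are delegated to
lifelines; the package adds its curve container, Greenwood variance
`Var[S] = S² Σ d/(n(n−d))` accumulated from the event table, pointwise
bands on the plain and log(−log) scales (the latter respects [0,1]
without clipping), and evaluation with the right-continuous step
convention (the value at the largest event time `<= t`).  Ties: events
precede censorings at equal times.  All-censored input returns the
constant-1 curve.

Landmark EFS re-zeroes each resected patient's clock at surgery
(`efs_months − surgery_months`) and stratifies by the pathologic
response determined there; unresected patients are excluded with a
warning.  EFS itself runs from treatment initiation to progression,
recurrence or death, censored at last imaging.

## Fixtures: what is data and what is reconstruction

Fixtures transcribe only printed quantities: the design constants,
stage-1 and total response counts (6→7 of 22, and 7→11 of 22), subgroup
denominators (17 and 16 patients without known EGFR/ALK alterations),
recurrence times (8.7, 17.7, 18.8, 19.5, 20.6, 21.7, 29.0, 30.4, 30.7,
35.7 months; and 8.3, 8.6, 9.6, 14.8 months), median follow-up (39.2 and
24.0 months) and landmark tallies (3/7 vs 7/15; 1/11 vs 3/9).
Reconstructions, all labelled as such in docstrings:

* which patient received which recurrence time (tally-preserving but
  otherwise arbitrary);
* covariate assignments, matching the published characteristics table
  margins only — cross-classifications are synthetic;
* censoring of non-event subjects at the arm's median follow-up;
* one death known only to fall within treatment cycle 1, encoded as
  1.5 months — any value below the earliest recurrence (8.3 months)
  yields identical 12- and 24-month survival estimates;
* a nominal 2.6-month treatment-to-surgery interval for landmark times;
* per-patient viable-tumor percentages are **not** invented: only pCR
  patients carry the definitional 0%, and the published medians live in
  aggregate form on the fixture set.

Display rounding matches the source report: percentages to one decimal,
round-half-away-from-zero.

## Synthetic generator

`simulate_trials` draws Bernoulli responses at a configurable true rate,
applies the futility stop, and enrolls the attained stage-2 size on
continuation.  One PCG64 generator seeded per run draws a fixed-width
`(n1 + n2)` row per replicate in row-major order, so replicate `i`
depends only on the seed and `i`: any prefix of a replicate table is
bit-identical across runs of different lengths.  `simulate_cohort` and
`simulate_survival_frame` add response-stratified exponential or Weibull
event times (responders at a reduced hazard, default ratio 0.5,
mirroring the premise of the landmark analysis), administrative
censoring, and an independent Bernoulli toxicity indicator.  Defaults —
a 1/36-per-month baseline hazard, 36-month administrative censoring, 10%
toxicity — are in the range typical of resectable-NSCLC event rates.

The generator emulates the probabilistic skeleton of such a trial, not
its clinical texture: no accrual process, no dropout beyond
administrative censoring, no dependence between response and toxicity,
and exchangeable patients.  Tests that pass on this generator therefore
validate the estimators' distributional properties (unbiasedness,
coverage, error rates), not robustness to covariate-driven structure in
real cohorts.

## Problem sizes used in the checks

The enumeration checks (UMVUE unbiasedness, CI coverage) run over the
complete outcome space of the 2/15 + 7 design (107 outcomes) on a
0.05-step probability grid.  Monte Carlo calibration uses 100,000
replicates for PET/power (3-SE criterion), 1,000 replicates of 50
subjects for log-rank p-value uniformity, and 10,000 subjects for the
exponential-median recovery check — sizes at which each check resolves
its target comfortably while the whole suite stays interactive.

## Known limitations

* Inference assumes the futility boundary was respected; outcomes that
  violate it are rejected rather than reinterpreted.
* The stagewise CI's default convention trades two-sided coverage for
  agreement with published practice (see above); users needing
  guaranteed coverage should request `method="equal-tail"`.
* A published 12-month survival figure for the first arm (96%) is not
  reproducible from printed information alone — it implies censoring
  detail never published — and is deliberately out of scope.
* No Cox regression, competing risks, interval censoring, multi-stage
  (>2) designs, or joint efficacy–toxicity monitoring.
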