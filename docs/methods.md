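# Methods

## The design problem

A two-arm randomized selection ("pick-the-winner") trial compares two
doses or regimens without a control arm and without formal type-I error
control.  The trial ends in one of three states: the hypothesized better
arm (arm 2) is observed superior, the two arms are practically
equivalent, or arm 2 is observed inferior.  Practical equivalence is
declared when the observed difference in median survival lies within the
margin of practical equivalence (MPE, in months); inside that margin the
selection falls to secondary criteria (toxicity, cost, convenience), and
under the indifference principle the better arm is still selected half
the time.  With state probabilities p_sup + p_equi + p_inf = 1, the
probability of correct selection at per-arm size n is

    pi_n(MPE) = p_sup + 0.5 * p_equi.

The design question is the smallest per-arm n for which pi_n(MPE)
reaches a threshold Q (0.80 by default):

    n_hat = min { n : pi_n(MPE) >= Q },   floored at n = 10.

`n` is always the per-arm size; total enrollment is 2n.

## Survival families

Event times follow one of three families, all parameterized by a shape
`alpha` and a **rate** `theta` (per month):

| family       | survival function          | median                              |
|--------------|----------------------------|-------------------------------------|
| exponential  | exp(-theta t)              | ln(2)/theta                         |
| Weibull      | exp(-(theta t)^alpha)      | theta^-1 (ln 2)^(1/alpha)           |
| genexp       | 1 - (1 - e^(-theta t))^alpha | -(1/theta) ln(1 - 0.5^(1/alpha)) |

The generalized exponential (genexp, the exponentiated exponential of
Gupta and Kundu) is a competing model to the gamma and Weibull with a
closed-form hazard and median; it reduces to the exponential at
alpha = 1, as does the Weibull.  Because `theta` is a rate everywhere,
the mapping to the common shape/scale convention is scale = 1/theta;
the module documents this to prevent silent inversions.  Sampling is by
inverse-CDF transform from a single seeded uniform stream (exact, no
rejection).

## Censoring

Non-informative right censoring: the observed data are (U, delta) with
U = min(T, C), delta = I(T <= C), and C independent of T.  The censoring
time is exponential, C ~ Exp(lambda), with lambda calibrated so the
marginal censored fraction P(C < T) = 1 - E[exp(-lambda T)] matches a
target (0-40% in the benchmark grids).  The expectation is evaluated by
adaptive quadrature (relative tolerance 1e-10) and lambda found by
bracketed root-finding on (1e-8, 1e3); for exponential event times the
closed form lambda = theta p/(1 - p) is used and doubles as a
calibration oracle in the tests.  Exponential censoring is the simplest
non-informative mechanism; the plan object keeps the mechanism as an
enum so alternatives can be added without API changes.  Administrative
censoring tied to accrual or follow-up windows is out of scope.

## Estimation

Each arm is fitted by maximizing the censored likelihood
prod_i g(u_i)^delta_i S(u_i)^(1-delta_i).  (For the genexp family this
censored form is used deliberately; a density-only likelihood would
ignore the censoring indicators and bias the medians downward.)

* **exponential** — closed form: theta_hat = r/W with r = sum(delta),
  W = sum(u); Var(theta_hat) ~ theta_hat^2 / r from the observed
  information r/theta^2.
* **Weibull** — profile likelihood: given alpha, the rate MLE is
  theta_hat(alpha) = (r / sum(u^alpha))^(1/alpha); the profile is
  maximized over log(alpha) in [log 0.1, log 20] (Brent-style bounded
  scalar minimization; golden-section in the vectorized batch path).
* **genexp** — 2-d quasi-Newton (L-BFGS-B; damped Newton in the batch
  path) on (log alpha, log theta) with the analytic score; box
  log-bounds alpha in [1e-3, 1e3].  Estimates on a bound are flagged
  as non-converged rather than returned silently.

The median is obtained by MLE invariance from the fitted parameters and
its standard error by the delta method: the analytic gradient of the
closed-form median (the rate component is -mu/theta in every family)
contracted with the inverse **observed** information — a numerical
Hessian of the negative log-likelihood at the MLE, central differences
of the analytic score with step max(1e-5, 1e-4 |x|).  An expected-
information variant (quadrature of E[score score^T] under the censoring
plan) provides a deterministic fast path for design calculations.

Within Monte-Carlo loops, replicates whose fit fails (no events, fewer
than two distinct event times, non-convergence, information matrix not
positive definite, or a boundary estimate) are dropped and the drop rate
reported; a rate above 20% is an error.  The vectorized batch fitters
are pinned against the scalar scipy-based fits in the test suite.

## Selection probability

Under the large-sample approximation mu_hat_k ~ N(mu_k, sigma_k^2),

    pi_n(MPE) = 1 - 0.5 Phi((MPE - D)/s) - 0.5 Phi((-MPE - D)/s),

with D = mu2 - mu1.  Two conventions for the combined scale s are
implemented and recorded with every result:

* `sum`: s = sigma_1 + sigma_2 — the design formula as commonly printed,
  and the package default;
* `rss`: s = sqrt(sigma_1^2 + sigma_2^2) — the exact standard deviation
  of mu_hat_2 - mu_hat_1 for independent arms.

The two differ by about sqrt(2) when the arms are comparable, which
roughly doubles the implied n, so the choice is consequential and is
always logged in the run manifest.  An empirical engine estimates pi_n
directly as the frequency of mu_hat_2 - mu_hat_1 exceeding +/-MPE over
simulated trials; it is the cross-check for the approximation.

The exponential model admits a fully closed form on the median scale:
Var(mu_hat_k) = (ln 2)^2 / (theta_k^2 n p) with p the event probability.
A rate-scale variant (margin applied to theta_hat_1 - theta_hat_2) is
provided as a clearly labelled alternative, since a rate margin is not
comparable to a margin in months.

## The sample-size search

The default (empirical) engine estimates, for each candidate n, the two
per-arm SEs as the average delta-method SE over `replicates` fits
(default 1000) and evaluates pi_n at the hypothesized medians.  Common
random numbers drive the whole n grid: one uniform matrix per stream is
drawn up front and candidate sizes reuse its leading columns, so pi_n
varies smoothly in n.  The grid is coarse (step 5) until the first
crossing; inside the bracket the SEs are interpolated as c/sqrt(n), and
the returned n_hat is re-verified (and its predecessor falsified) by
direct fits.  The threshold is inclusive (pi >= Q), and results at the
floor n = 10 carry a `floored` flag.  With 1000 replicates the Monte-
Carlo error on an averaged-SE pi near 0.8 is about 0.002-0.005, leaving
n_hat stable to roughly +/-1 patient across seeds.

The `expected_info` engine replaces the Monte-Carlo SEs with the
deterministic expected-information SEs and scans integers directly; it
agrees with the empirical engine within a few patients (tested at
+/-15%) and is the right tool for quick scenario exploration.

## Benchmark grids and a reproduction note

The harness ships four benchmark grids reproducing published-style
design tables: Weibull and genexp families, arm 1 anchored at
(shape 2, rate 0.10) — median 8.3 months (genexp: 12.3) — or
(shape 1.5, rate 0.12) — median 6.5 months (genexp: 8.3) — with arm-2
shapes swept over 1.5-3.0 and rates over 0.08-0.11, MPE = 1 month,
Q = 0.80, censoring 0-40%.  The genexp arm-1 anchors are chosen so the
quoted arm-1 medians and the quoted five-month gap to arm 2 at
(2.4, 0.08) are reproduced exactly.

Reproducing the reference tables exposed an inconsistency that users
should know about.  With SEs verified against the replicate scatter of
the fitted medians (they agree within a few percent for both families):

* the Weibull reference values (71/72/75/81/88 for the (2, 0.10) vs
  (2.4, 0.09) scenario) are matched by the **rss** scale — this package
  computes 69/73/78/85/94 — while the `sum` scale would roughly double
  them;
* the genexp reference values are matched at 0-10% censoring by the
  **sum** scale (33/35 vs 34/39) but not at 20-40% censoring
  (38/42/48 computed vs 45/53/67), under every mechanism we examined
  (exponential, uniform, and fixed-time censoring, and a
  censoring-ignored likelihood).

No single procedure reproduces both families, so each benchmark grid
records the convention its reference table is consistent with (Weibull
grids: `rss`; genexp grids: `sum`), and the heavy-censoring genexp
cells remain an open discrepancy: the reference values grow faster with
censoring than the information content of the censored samples can
explain.  Design work with this package should prefer `rss`, which is
the statistically correct scale for independent arms; `sum` is retained
as the default for continuity with the printed design formula and
because every result object names the convention used.

## What the synthetic generator does and does not emulate

It draws i.i.d. event times from the chosen family and independent
exponential censoring calibrated to a marginal fraction — exactly the
sampling model assumed by the estimators.  It does not model staggered
accrual, administrative cut-offs, dependent or informative censoring,
covariate effects, cure fractions, or non-monotone hazards.  Passing
tests therefore certify the internal consistency of the design
machinery under its own assumptions, not robustness to real-trial
departures from them; for hazard shapes outside these families the
empirical engine can be pointed at user-supplied scenarios, but the
families themselves are the model.

## Numerical choices

* Optimizer bounds: log alpha in [log 0.1, log 20] (Weibull profile),
  [log 1e-3, log 1e3] (genexp); boundary solutions flagged.
* Hessian steps: central differences with step max(1e-5, 1e-4 |x|) on
  the natural (alpha, theta) scale.
* Quadrature: adaptive, relative tolerance 1e-9 to 1e-10; censoring
  calibration root bracketed on (1e-8, 1e3).
* Search: coarse step 5, inclusive threshold, floor 10, default
  n_max = 2000; ties cannot occur (pi is continuous in n through the
  SE scale).
* Seeds: a single integer seed drives generation, censoring, and the
  whole search; identical seeds reproduce n_hat exactly.
* Benchmark problem sizes: 1000 replicates per candidate n, chosen so
  the Monte-Carlo jitter in n_hat (about +/-1 patient) is far below the
  benchmark tolerance.

## Known limitations

* Three-arm selection, interim analyses, and co-primary
  toxicity/quality-of-life criteria are out of scope.
* Gamma, generalized-gamma, and log-normal families are not implemented.
* The large-sample pi formula treats the fitted medians as normal;
  at very small n (near the floor of 10) and heavy censoring the genexp
  median estimate is noticeably skewed, which is why the empirical
  engine and the drop-rate reporting exist.
* The heavy-censoring genexp benchmark cells discussed above.
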