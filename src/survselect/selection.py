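"""Probability of correct selection pi_n(MPE) for two-arm selection trials.

A selection trial ends in one of three states: the hypothesized better
arm (arm 2) is observed superior by more than the margin of practical
equivalence (MPE), the two arms are practically equivalent, or arm 2 is
observed inferior.  With p_sup + p_equi + p_inf = 1, the probability of
selecting the truly better arm under the indifference principle is

    pi = p_sup + 0.5 * p_equi

Under the large-sample normal approximation for the fitted medians,
mu_hat_k ~ N(mu_k, sigma_k^2),

    pi_n(MPE) = 1 - 0.5*Phi((MPE - D)/s) - 0.5*Phi((-MPE - D)/s)

with D = mu2 - mu1 and s a combined scale of the two median SEs.  Two
conventions for s are supported:

* ``"sum"``   — s = sigma1 + sigma2 (the design formula used here as the
  default);
* ``"rss"``   — s = sqrt(sigma1^2 + sigma2^2), the exact scale of
  mu_hat_2 - mu_hat_1 for independent arms.

The empirical counterpart simulates whole trials (generation, censoring,
per-arm fits) and averages the three state frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .censoring import calibrate_censoring
from .distributions import DistributionSpec, median, quantile
from .mle import EstimationError, fit_batch

__all__ = [
    "SE_COMBINE_MODES",
    "TrialScenario",
    "SelectionProbability",
    "combine_se",
    "pi_normal_approx",
    "pi_empirical",
    "pi_exponential",
]

SE_COMBINE_MODES = ("sum", "rss")


@dataclass(frozen=True)
class TrialScenario:
    """Two arms plus design constants (MPE, threshold Q, censoring, MC)."""

    arm1: DistributionSpec
    arm2: DistributionSpec
    mpe: float
    q_threshold: float = 0.80
    censoring_fraction: float = 0.0
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mpe < 0:
            raise ValueError("mpe must be nonnegative (months)")
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must lie in (0, 1)")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must lie in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")
        if median(self.arm2) < median(self.arm1):
            raise ValueError(
                "arm 2 must be the hypothesized better dose: "
                "median(arm2) >= median(arm1)"
            )

    @property
    def median_difference(self) -> float:
        return median(self.arm2) - median(self.arm1)


@dataclass(frozen=True)
class SelectionProbability:
    """The three trial-state probabilities and pi = p_sup + 0.5*p_equi."""

    p_sup: float
    p_equi: float
    p_inf: float
    pi: float
    method: str  # "normal_approx" | "empirical"

    def __post_init__(self) -> None:
        tot = self.p_sup + self.p_equi + self.p_inf
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"state probabilities sum to {tot}, not 1")
        if abs(self.pi - (self.p_sup + 0.5 * self.p_equi)) > 1e-9:
            raise ValueError("pi must equal p_sup + 0.5 * p_equi")


def combine_se(se1: float, se2: float, se_combine: str = "sum") -> float:
    """Combined scale of the median difference under the chosen convention."""
    if se_combine not in SE_COMBINE_MODES:
        raise ValueError(f"se_combine must be one of {SE_COMBINE_MODES}")
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    return se1 + se2 if se_combine == "sum" else float(np.hypot(se1, se2))


def pi_normal_approx(
    mu1: float,
    mu2: float,
    se1: float,
    se2: float,
    mpe: float,
    se_combine: str = "sum",
) -> SelectionProbability:
    """Large-sample normal approximation to the selection probability."""
    if mpe < 0:
        raise ValueError("mpe must be nonnegative")
    s = combine_se(se1, se2, se_combine)
    delta = mu2 - mu1
    p_sup = 1.0 - stats.norm.cdf((mpe - delta) / s)
    p_inf = stats.norm.cdf((-mpe - delta) / s)
    p_equi = stats.norm.cdf((mpe - delta) / s) - stats.norm.cdf((-mpe - delta) / s)
    pi = p_sup + 0.5 * p_equi
    return SelectionProbability(
        float(p_sup), float(p_equi), float(p_inf), float(pi), "normal_approx"
    )


def _simulate_arm_matrix(
    spec: DistributionSpec,
    censoring_fraction: float,
    replicates: int,
    n: int,
    rng: np.random.Generator,
):
    """(replicates, n) matrices of observed times and event indicators."""
    ut = rng.uniform(size=(replicates, n))
    ut[ut == 0.0] = np.nextafter(0.0, 1.0)
    t = quantile(spec, ut)
    if censoring_fraction == 0.0:
        return t, np.ones_like(t)
    plan = calibrate_censoring(spec, censoring_fraction)
    c = rng.exponential(scale=1.0 / plan.censor_rate, size=(replicates, n))
    return np.minimum(t, c), (t <= c).astype(float)


def pi_empirical(
    scenario: TrialScenario,
    n: int,
    max_failure_rate: float = 0.20,
) -> SelectionProbability:
    """Monte-Carlo selection probability at per-arm size ``n``.

    Each replicate simulates both arms (with censoring), fits each by
    censored ML, and classifies mu_hat_2 - mu_hat_1 against +/-MPE; the
    three state frequencies are averaged over replicates.  Replicates in
    which either arm's fit fails are dropped; a drop rate above
    ``max_failure_rate`` raises :class:`EstimationError`.
    """
    if n < 10:
        raise ValueError("n below the minimum fit size of 10")
    rng = np.random.default_rng(scenario.seed)
    reps = scenario.replicates
    u1, d1 = _simulate_arm_matrix(
        scenario.arm1, scenario.censoring_fraction, reps, n, rng
    )
    u2, d2 = _simulate_arm_matrix(
        scenario.arm2, scenario.censoring_fraction, reps, n, rng
    )
    fit1 = fit_batch(scenario.arm1.family, u1, d1)
    fit2 = fit_batch(scenario.arm2.family, u2, d2)
    keep = fit1.ok & fit2.ok
    fail_rate = 1.0 - keep.mean()
    if fail_rate > max_failure_rate:
        raise EstimationError(
            f"replicate fit-failure rate {fail_rate:.1%} exceeds "
            f"{max_failure_rate:.0%}"
        )
    diff = fit2.median[keep] - fit1.median[keep]
    p_sup = float(np.mean(diff > scenario.mpe))
    p_inf = float(np.mean(diff < -scenario.mpe))
    p_equi = 1.0 - p_sup - p_inf
    pi = p_sup + 0.5 * p_equi
    return SelectionProbability(p_sup, p_equi, p_inf, pi, "empirical")


def pi_exponential(
    theta1: float,
    theta2: float,
    n: int,
    p_event: float,
    mpe: float,
    se_combine: str = "sum",
    scale: str = "median",
) -> SelectionProbability:
    """Closed-form exponential-model selection probability.

    Works on the median-difference scale by default: the median of
    Exp(theta) is ln(2)/theta and the delta method gives
    Var(mu_hat_k) = ln(2)^2 / (theta_k^2 * n * p_event), with p_event the
    non-censoring probability.  ``scale="rate"`` is a clearly labelled
    alternative that applies the same margin on the rate-difference scale
    (Var(theta_hat_k) = theta_k^2 / (n * p_event)); the MPE is then a
    rate margin, not months.
    """
    if theta2 > theta1:
        raise ValueError("requires theta1 >= theta2 (arm 2 has the longer median)")
    if not 0.0 < p_event <= 1.0:
        raise ValueError("p_event must lie in (0, 1]")
    if n < 1:
        raise ValueError("n must be positive")
    if scale == "median":
        mu1 = np.log(2.0) / theta1
        mu2 = np.log(2.0) / theta2
        se1 = mu1 / np.sqrt(n * p_event)
        se2 = mu2 / np.sqrt(n * p_event)
        return pi_normal_approx(mu1, mu2, se1, se2, mpe, se_combine)
    if scale == "rate":
        se1 = theta1 / np.sqrt(n * p_event)
        se2 = theta2 / np.sqrt(n * p_event)
        # arm 2 is better when theta2 < theta1: the "superior" direction
        # is a rate *decrease*, so compare theta1 - theta2 to the margin
        return pi_normal_approx(theta2, theta1, se2, se1, mpe, se_combine)
    raise ValueError("scale must be 'median' or 'rate'")
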