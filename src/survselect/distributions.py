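"""Parametric survival families used for selection-trial design.

Three two-parameter families are supported, all parameterized by a shape
``alpha`` and a *rate* ``theta`` (per month):

``exponential``
    S(t) = exp(-theta*t); shape is fixed to 1.
``weibull``
    S(t) = exp(-(theta*t)**alpha), i.e. scale = 1/theta in the usual
    shape/scale convention (``scipy.stats.weibull_min(c=alpha,
    scale=1/theta)``).
``genexp``
    The generalized (exponentiated) exponential of Gupta and Kundu, with
    CDF F(t) = (1 - exp(-theta*t))**alpha.  It reduces to the exponential
    when alpha = 1 and is a competing model to the gamma and Weibull with
    a closed-form hazard and median.

Because theta is a rate everywhere, the closed-form medians are

    exponential:  ln(2) / theta
    weibull:      theta**-1 * ln(2)**(1/alpha)
    genexp:       -(1/theta) * ln(1 - 0.5**(1/alpha))

Mapping to scale parameterizations (scale = 1/theta) is exact; the rate
convention is used throughout to avoid silent inversions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "density",
    "survival",
    "cdf",
    "hazard",
    "median",
    "quantile",
    "sample_times",
]

FAMILIES = ("exponential", "weibull", "genexp")

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class DistributionSpec:
    """A survival distribution: family tag, shape ``alpha``, rate ``theta``.

    For the exponential family the shape is fixed to 1 and ignored.
    Time unit is months.
    """

    family: str
    rate: float
    shape: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise ValueError(f"rate must be a positive real, got {self.rate}")
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError(f"shape must be a positive real, got {self.shape}")
        if self.family == "exponential" and self.shape != 1.0:
            raise ValueError("exponential family has shape fixed to 1")

    @property
    def scale(self) -> float:
        """Scale parameter 1/rate (months), for the shape/scale convention."""
        return 1.0 / self.rate


def _frozen(spec: DistributionSpec):
    # scipy backs the exponential and Weibull; genexp is implemented here.
    if spec.family == "exponential":
        return stats.expon(scale=1.0 / spec.rate)
    if spec.family == "weibull":
        return stats.weibull_min(c=spec.shape, scale=1.0 / spec.rate)
    return None


def _check_t(t, allow_zero: bool) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    bad = (t < 0) | (~np.isfinite(t)) if allow_zero else (t <= 0) | (~np.isfinite(t))
    if np.any(bad):
        raise ValueError("time values must be positive reals")
    return t


def density(spec: DistributionSpec, t) -> np.ndarray | float:
    """Density g(t) of the family at time ``t > 0`` (vectorized)."""
    t = _check_t(t, allow_zero=False)
    fr = _frozen(spec)
    if fr is not None:
        out = fr.pdf(t)
    else:
        a, th = spec.shape, spec.rate
        x = th * t
        # (1 - e^-x)^(a-1) via expm1 for small-x stability
        out = a * th * np.exp(-x + (a - 1.0) * np.log(-np.expm1(-x)))
    return out if out.ndim else float(out)


def cdf(spec: DistributionSpec, t) -> np.ndarray | float:
    """CDF F(t) at ``t >= 0`` (vectorized)."""
    t = _check_t(t, allow_zero=True)
    fr = _frozen(spec)
    if fr is not None:
        out = fr.cdf(t)
    else:
        a, th = spec.shape, spec.rate
        with np.errstate(divide="ignore"):
            out = np.where(t > 0, np.exp(a * np.log(-np.expm1(-th * t))), 0.0)
    return out if out.ndim else float(out)


def survival(spec: DistributionSpec, t) -> np.ndarray | float:
    """Survival function S(t) = 1 - F(t) at ``t >= 0`` (vectorized)."""
    t = _check_t(t, allow_zero=True)
    fr = _frozen(spec)
    if fr is not None:
        out = fr.sf(t)
    else:
        a, th = spec.shape, spec.rate
        with np.errstate(divide="ignore"):
            logF = np.where(t > 0, a * np.log(-np.expm1(-th * t)), -np.inf)
        out = -np.expm1(logF)
    return out if out.ndim else float(out)


def hazard(spec: DistributionSpec, t) -> np.ndarray | float:
    """Hazard g(t)/S(t) at ``t > 0`` (vectorized)."""
    t = _check_t(t, allow_zero=False)
    return density(spec, t) / survival(spec, t)


def median(spec: DistributionSpec) -> float:
    """Closed-form median survival time (months)."""
    a, th = spec.shape, spec.rate
    if spec.family == "exponential":
        return _LN2 / th
    if spec.family == "weibull":
        return _LN2 ** (1.0 / a) / th
    return -np.log(1.0 - 0.5 ** (1.0 / a)) / th


def quantile(spec: DistributionSpec, u) -> np.ndarray | float:
    """Inverse CDF at probability ``u`` in (0, 1) (vectorized)."""
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1) | ~np.isfinite(u)):
        raise ValueError("quantile probabilities must lie strictly in (0, 1)")
    fr = _frozen(spec)
    if fr is not None:
        out = fr.ppf(u)
    else:
        a, th = spec.shape, spec.rate
        out = -np.log(1.0 - u ** (1.0 / a)) / th
    return out if out.ndim else float(out)


def sample_times(
    spec: DistributionSpec,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. event times by inverse-CDF sampling.

    A single uniform stream drives the draw, so results are exactly
    reproducible for a fixed integer seed.
    """
    if int(n) < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.uniform(size=int(n))
    # u = 0 has measure zero but would fail quantile validation
    u[u == 0.0] = np.nextafter(0.0, 1.0)
    return np.atleast_1d(np.asarray(quantile(spec, u), dtype=float))
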