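"""Parametric sampling recipes for model input variables.

Every model input is described by a :class:`DistributionSpec` — a family
name, its parameters, and an optional truncation interval.  Families follow
the conventions common in probabilistic exposure modelling:

``point``
    a degenerate distribution (the value itself);
``uniform``
    parameterized by (min, max);
``normal``
    (mean, SD);
``lognormal``
    (geometric mean, geometric SD) — GM is the median, log(GSD) the SD of
    the log;
``beta``
    (alpha, beta) with an optional third scale parameter;
``exponential``
    a *bounded* exponential given by (min, mean, max): the distribution is
    an exponential truncated to [min, max] whose rate is solved numerically
    so the truncated mean equals the stated mean.

Truncation is applied by rejection resampling (falling back to clipping
only after a large number of rejected draws), so truncated distributions
remain continuous with no point mass at the bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

__all__ = ["DistributionSpec", "SpecError", "FAMILIES"]

FAMILIES = ("point", "uniform", "normal", "lognormal", "beta", "exponential")

_MAX_REJECT = 1000


class SpecError(ValueError):
    """Invalid distribution specification."""


@lru_cache(maxsize=None)
def _bounded_expon_rate(lo: float, mean: float, hi: float) -> float:
    """Rate of an exponential truncated to [lo, hi] with the given mean.

    The truncated mean decreases monotonically from (lo + hi)/2 (rate -> 0,
    the uniform limit) to lo (rate -> inf), so a unique solution exists for
    lo < mean < (lo + hi)/2.
    """
    span = hi - lo
    target = mean - lo

    def f(lam: float) -> float:
        x = lam * span
        tail = 0.0 if x > 700.0 else span / math.expm1(x)
        return 1.0 / lam - tail - target

    return optimize.brentq(f, 1e-12, 1e4, xtol=1e-14, rtol=1e-14)


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling recipe: family, parameters, optional truncation, units."""

    family: str
    params: tuple[float, ...]
    truncation: tuple[float, float] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.truncation is not None:
            lo, hi = (float(b) for b in self.truncation)
            object.__setattr__(self, "truncation", (lo, hi))
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        f, p = self.family, self.params
        if f not in FAMILIES:
            raise SpecError(f"unknown distribution family {f!r}")
        n = len(p)
        if f == "point" and n != 1:
            raise SpecError("point takes exactly one parameter")
        if f == "uniform":
            if n != 2:
                raise SpecError("uniform takes (min, max)")
            if not p[0] < p[1]:
                raise SpecError(f"uniform requires min < max, got {p}")
        if f == "normal":
            if n != 2:
                raise SpecError("normal takes (mean, sd)")
            if not p[1] > 0:
                raise SpecError(f"normal requires sd > 0, got sd={p[1]}")
        if f == "lognormal":
            if n != 2:
                raise SpecError("lognormal takes (GM, GSD)")
            if not p[0] > 0:
                raise SpecError(f"lognormal requires GM > 0, got {p[0]}")
            if not p[1] > 1:
                raise SpecError(f"lognormal requires GSD > 1, got {p[1]}")
        if f == "beta":
            if n not in (2, 3):
                raise SpecError("beta takes (alpha, beta[, scale])")
            if p[0] <= 0 or p[1] <= 0:
                raise SpecError(f"beta requires alpha, beta > 0, got {p}")
            if n == 3 and p[2] <= 0:
                raise SpecError(f"beta scale must be > 0, got {p[2]}")
        if f == "exponential":
            if n != 3:
                raise SpecError("exponential takes (min, mean, max)")
            lo, mean, hi = p
            if not lo < hi:
                raise SpecError(f"exponential requires min < max, got {p}")
            if not lo < mean < (lo + hi) / 2:
                raise SpecError(
                    "bounded exponential requires min < mean < (min+max)/2, "
                    f"got {p}"
                )
        if self.truncation is not None:
            lo, hi = self.truncation
            if not lo < hi:
                raise SpecError(f"truncation bounds must be ordered, got {self.truncation}")

    # -- support / frozen scipy distribution -----------------------------

    def support(self) -> tuple[float, float]:
        """Effective support: the natural support intersected with truncation."""
        f, p = self.family, self.params
        if f == "point":
            lo = hi = p[0]
        elif f == "uniform":
            lo, hi = p
        elif f == "normal":
            lo, hi = -math.inf, math.inf
        elif f == "lognormal":
            lo, hi = 0.0, math.inf
        elif f == "beta":
            lo, hi = 0.0, p[2] if len(p) == 3 else 1.0
        else:  # exponential
            lo, hi = p[0], p[2]
        if self.truncation is not None:
            lo = max(lo, self.truncation[0])
            hi = min(hi, self.truncation[1])
        return lo, hi

    def _frozen(self):
        f, p = self.family, self.params
        if f == "uniform":
            return stats.uniform(loc=p[0], scale=p[1] - p[0])
        if f == "normal":
            return stats.norm(loc=p[0], scale=p[1])
        if f == "lognormal":
            return stats.lognorm(s=math.log(p[1]), scale=p[0])
        if f == "beta":
            scale = p[2] if len(p) == 3 else 1.0
            return stats.beta(p[0], p[1], loc=0.0, scale=scale)
        if f == "exponential":
            lo, _, hi = p
            lam = _bounded_expon_rate(*p)
            return stats.truncexpon((hi - lo) * lam, loc=lo, scale=1.0 / lam)
        raise SpecError(f"no frozen form for family {f!r}")

    # -- sampling --------------------------------------------------------

    def _draw(self, rng: np.random.Generator) -> float:
        f, p = self.family, self.params
        if f == "uniform":
            return rng.uniform(p[0], p[1])
        if f == "normal":
            return rng.normal(p[0], p[1])
        if f == "lognormal":
            return math.exp(rng.normal(math.log(p[0]), math.log(p[1])))
        if f == "beta":
            scale = p[2] if len(p) == 3 else 1.0
            return rng.beta(p[0], p[1]) * scale
        # bounded exponential via inverse CDF on [lo, hi]
        lo, _, hi = p
        lam = _bounded_expon_rate(*p)
        u = rng.random()
        return lo - math.log1p(-u * (-math.expm1(-lam * (hi - lo)))) / lam

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one value, honouring truncation by rejection resampling."""
        if self.family == "point":
            return self.params[0]
        if self.truncation is None:
            return float(self._draw(rng))
        lo, hi = self.truncation
        for _ in range(_MAX_REJECT):
            x = self._draw(rng)
            if lo <= x <= hi:
                return float(x)
        return float(min(max(self._draw(rng), lo), hi))

    # -- analytic summaries ----------------------------------------------

    def cdf(self, x: float) -> float:
        if self.family == "point":
            return 0.0 if x < self.params[0] else 1.0
        return float(self._frozen().cdf(x))

    def ppf(self, q: float) -> float:
        """Quantile of the (truncated) distribution."""
        if not 0.0 <= q <= 1.0:
            raise SpecError(f"quantile must be in [0, 1], got {q}")
        if self.family == "point":
            return self.params[0]
        d = self._frozen()
        if self.truncation is None:
            return float(d.ppf(q))
        lo, hi = self.truncation
        a, b = float(d.cdf(lo)), float(d.cdf(hi))
        return float(d.ppf(a + q * (b - a)))

    def median(self) -> float:
        """Analytical median of the (truncated) distribution."""
        return self.ppf(0.5)

    def mean(self) -> float:
        """Mean of the (truncated) distribution."""
        if self.family == "point":
            return self.params[0]
        d = self._frozen()
        if self.truncation is None:
            return float(d.mean())
        lo, hi = self.truncation
        mass = float(d.cdf(hi) - d.cdf(lo))
        if mass <= 0:
            raise SpecError("truncation interval has zero probability mass")
        return float(d.expect(lambda x: x, lb=lo, ub=hi)) / mass
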