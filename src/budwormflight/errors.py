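"""Deviate families for the flight models.

Three families describe individual variation around a predicted mean:

* additive normal errors, ``y = mu + eps`` with ``eps ~ N(0, sigma2)``;
* multiplicative lognormal deviates with mean one, ``y = mu * delta``;
* multiplicative Weibull deviates with mean one, ``y = mu * xi`` where
  ``xi ~ Weibull(kappa, lambda)`` and the scale is tied to the shape as
  ``lambda = 1 / Gamma(1 + 1/kappa)`` so that ``E[xi] = 1``.  The
  exponential distribution is the special case ``kappa = lambda = 1``.

The mean-one constraint makes the multiplicative families natural for
heteroscedastic, strictly positive responses: the mean function carries
all systematic structure and the deviate carries relative scatter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "ErrorFamily",
    "NormalAdditive",
    "LognormalMultiplicative",
    "WeibullMultiplicative",
    "mean1_weibull_scale",
    "get_family",
    "expected_cumfreq",
]

_LOG_2PI = math.log(2.0 * math.pi)


def mean1_weibull_scale(kappa: float) -> float:
    """Scale ``lambda`` giving a Weibull(kappa, lambda) mean of exactly 1.

    ``lambda = 1 / Gamma(1 + 1/kappa)``.  Raises ``ValueError`` for
    ``kappa <= 0``.
    """
    if kappa <= 0:
        raise ValueError(f"Weibull shape must be positive, got {kappa}")
    return 1.0 / special.gamma(1.0 + 1.0 / kappa)


@dataclass(frozen=True)
class ErrorFamily:
    """Base class: a deviate model with at most one free shape parameter."""

    #: number of free distributional parameters counted in k for AICc
    n_shape: int = 1
    #: short name used in reports and configs
    name: str = ""
    #: True when deviates multiply the mean (requires y > 0, mu > 0)
    multiplicative: bool = False

    def nll(self, y: np.ndarray, mu: np.ndarray, shape: float) -> float:
        raise NotImplementedError

    def sample(self, mu: np.ndarray, shape: float, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def deviates(self, y: np.ndarray, mu: np.ndarray) -> np.ndarray:
        """Observed deviates: residuals ``y - mu`` or ratios ``y / mu``."""
        y = np.asarray(y, dtype=float)
        mu = np.asarray(mu, dtype=float)
        return y / mu if self.multiplicative else y - mu

    def deviate_cdf(self, x: np.ndarray, shape: float) -> np.ndarray:
        """CDF of the deviate distribution at ``x`` given the shape."""
        raise NotImplementedError

    def init_shape(self, deviates: np.ndarray) -> float:
        """Method-of-moments starting value for the shape parameter."""
        raise NotImplementedError


@dataclass(frozen=True)
class NormalAdditive(ErrorFamily):
    n_shape: int = 1
    name: str = "normal"
    multiplicative: bool = False

    def nll(self, y, mu, shape):
        sigma2 = shape
        if sigma2 <= 0:
            return np.inf
        r = np.asarray(y, float) - np.asarray(mu, float)
        n = r.size
        return 0.5 * (n * (_LOG_2PI + math.log(sigma2)) + float(r @ r) / sigma2)

    def sample(self, mu, shape, rng):
        return np.asarray(mu, float) + rng.normal(0.0, math.sqrt(shape), size=np.shape(mu))

    def deviate_cdf(self, x, shape):
        return stats.norm.cdf(x, loc=0.0, scale=math.sqrt(shape))

    def init_shape(self, deviates):
        v = float(np.var(deviates))
        return v if v > 0 else 1e-8


@dataclass(frozen=True)
class LognormalMultiplicative(ErrorFamily):
    """Mean-one lognormal deviate.

    The shape parameter is the log-scale variance sigma2; the log-scale
    mean is tied to ``-sigma2/2`` so that ``E[delta] = 1``.
    """

    n_shape: int = 1
    name: str = "lognormal"
    multiplicative: bool = True

    def nll(self, y, mu, shape):
        sigma2 = shape
        y = np.asarray(y, float)
        mu = np.asarray(mu, float)
        if sigma2 <= 0 or np.any(mu <= 0) or np.any(y <= 0):
            return np.inf
        z = np.log(y) - np.log(mu) + 0.5 * sigma2
        n = y.size
        return 0.5 * (n * (_LOG_2PI + math.log(sigma2)) + float(z @ z) / sigma2) + float(
            np.sum(np.log(y))
        )

    def sample(self, mu, shape, rng):
        s = math.sqrt(shape)
        return np.asarray(mu, float) * rng.lognormal(-0.5 * shape, s, size=np.shape(mu))

    def deviate_cdf(self, x, shape):
        s = math.sqrt(shape)
        return stats.lognorm.cdf(x, s, scale=math.exp(-0.5 * shape))

    def init_shape(self, deviates):
        d = np.asarray(deviates, float)
        d = d[d > 0]
        v = float(np.var(np.log(d)))
        return v if v > 0 else 1e-8


@dataclass(frozen=True)
class WeibullMultiplicative(ErrorFamily):
    """Mean-one Weibull deviate; scale is never free (see mean1_weibull_scale)."""

    n_shape: int = 1
    name: str = "weibull"
    multiplicative: bool = True
    #: when set, kappa is held fixed at this value (exponential: 1.0)
    fixed_kappa: float | None = None

    def nll(self, y, mu, shape):
        kappa = self.fixed_kappa if self.fixed_kappa is not None else shape
        y = np.asarray(y, float)
        mu = np.asarray(mu, float)
        if kappa <= 0 or np.any(mu <= 0) or np.any(y <= 0):
            return np.inf
        lam = mean1_weibull_scale(kappa)
        # density of y = mu * xi: (kappa/(lam*mu)) (y/(lam*mu))^(kappa-1) exp(-(y/(lam*mu))^kappa)
        s = lam * mu
        z = y / s
        logpdf = math.log(kappa) - np.log(s) + (kappa - 1.0) * np.log(z) - z**kappa
        return -float(np.sum(logpdf))

    def sample(self, mu, shape, rng):
        kappa = self.fixed_kappa if self.fixed_kappa is not None else shape
        lam = mean1_weibull_scale(kappa)
        xi = lam * rng.weibull(kappa, size=np.shape(mu))
        return np.asarray(mu, float) * xi

    def deviate_cdf(self, x, shape):
        kappa = self.fixed_kappa if self.fixed_kappa is not None else shape
        lam = mean1_weibull_scale(kappa)
        x = np.asarray(x, float)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = 1.0 - np.exp(-((x[pos] / lam) ** kappa))
        return out

    def init_shape(self, deviates):
        if self.fixed_kappa is not None:
            return self.fixed_kappa
        d = np.asarray(deviates, float)
        d = d[d > 0]
        cv = float(np.std(d) / np.mean(d))
        # CV of Weibull(kappa) = sqrt(G2/G1^2 - 1), G_j = Gamma(1 + j/kappa);
        # invert numerically on a coarse grid then refine by bisection.
        from scipy.optimize import brentq

        def f(k):
            g1 = special.gamma(1 + 1 / k)
            g2 = special.gamma(1 + 2 / k)
            return math.sqrt(max(g2 / g1**2 - 1.0, 1e-12)) - cv

        try:
            return brentq(f, 0.05, 80.0)
        except ValueError:
            return 1.0


_FAMILIES = {
    "normal": NormalAdditive(),
    "lognormal": LognormalMultiplicative(),
    "weibull": WeibullMultiplicative(),
    "exponential": WeibullMultiplicative(fixed_kappa=1.0, n_shape=0, name="exponential"),
}


def get_family(name: str) -> ErrorFamily:
    """Look up a family by name: normal | lognormal | weibull | exponential."""
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown error family {name!r}; choose from {sorted(_FAMILIES)}")


def expected_cumfreq(family: ErrorFamily, deviates: np.ndarray, shape: float):
    """Observed vs expected cumulative frequencies of deviates.

    Sorts the deviates, assigns plotting positions ``(i - 0.5) / n`` as the
    observed cumulative frequencies, evaluates the family CDF of the deviate
    distribution at the sorted values, and returns
    ``(observed, expected, pearson_r)``.  This correlation is the criterion
    used to choose among candidate deviate distributions.
    """
    d = np.sort(np.asarray(deviates, dtype=float))
    n = d.size
    if n < 10:
        raise ValueError("need at least 10 deviates for a cumulative-frequency comparison")
    if family.multiplicative and np.any(d <= 0):
        raise ValueError("non-positive deviate under a multiplicative family")
    if np.ptp(d) == 0:
        raise ValueError("constant deviates: cumulative-frequency correlation undefined")
    obs = (np.arange(1, n + 1) - 0.5) / n
    exp = family.deviate_cdf(d, shape)
    r = float(np.corrcoef(obs, exp)[0, 1])
    return obs, exp, r
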