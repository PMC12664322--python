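"""Box-Cox normalization, Anderson-Darling screening, and temperature-term pre-fits.

Before predictor screening, each strictly positive response is normalized
as far as possible with a Box-Cox power transform whose exponent is chosen
to maximize the Anderson-Darling normality p-value.  Curvilinear
temperature effects are summarized by one of three simple terms fitted in
advance -- ``1/T^2``, a saturating ``T/(T0+T)``, or a quadratic
``(T-T0)^2`` -- whose fitted optimum ``T0`` seeds the full model fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TempTerm",
    "box_cox",
    "inv_box_cox",
    "anderson_darling",
    "choose_box_cox",
    "prefit_temp_term",
]

_FORMS = ("inverse_square", "saturating", "quadratic")


@dataclass
class TempTerm:
    """A pre-fitted temperature transformation used in place of raw T."""

    form: str  # inverse_square | saturating | quadratic
    T0: float | None = None  # optimum / half-saturation, degC

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"unknown temperature term {self.form!r}")
        if self.form != "inverse_square" and self.T0 is None:
            raise ValueError(f"{self.form} temperature term requires T0")

    def __call__(self, T, T0: float | None = None):
        T = np.asarray(T, dtype=float)
        if self.form == "inverse_square":
            return 1.0 / T**2
        t0 = self.T0 if T0 is None else T0
        if self.form == "saturating":
            return T / (t0 + T)
        return (T - t0) ** 2

    @property
    def has_T0(self) -> bool:
        return self.form != "inverse_square"


def box_cox(y, lam: float):
    """Box-Cox transform ``(y^lam - 1)/lam`` (natural log when lam == 0)."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lam == 0:
        return np.log(y)
    # expm1 keeps the transform accurate for |lam| near 0
    return np.expm1(lam * np.log(y)) / lam


def inv_box_cox(z, lam: float):
    """Exact inverse of :func:`box_cox`."""
    z = np.asarray(z, dtype=float)
    if lam == 0:
        return np.exp(z)
    return np.exp(np.log1p(lam * z) / lam)


def anderson_darling(y) -> tuple[float, float]:
    """Anderson-Darling composite normality test: returns (A2, p).

    A2 carries the small-sample correction ``(1 + 0.75/n + 2.25/n^2)``;
    the p-value uses the standard approximation for the case where both
    mean and variance are estimated.  Constant input raises ``ValueError``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 8:
        raise ValueError("Anderson-Darling test requires n >= 8")
    if np.ptp(y) == 0:
        raise ValueError("constant sample: normality test undefined")
    z = np.sort((y - y.mean()) / y.std(ddof=1))
    cdf = np.clip(stats.norm.cdf(z), 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1])))
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2s >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s**2)
    elif a2s > 0.34:
        p = math.exp(0.9177 - 4.279 * a2s - 1.38 * a2s**2)
    elif a2s > 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2s - 59.938 * a2s**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2s - 223.73 * a2s**2)
    return float(a2s), float(min(max(p, 0.0), 1.0))


def choose_box_cox(y, grid=None) -> tuple[float, float, float]:
    """Pick the Box-Cox exponent maximizing the Anderson-Darling p-value.

    Returns ``(lam, A2, p)`` at the best grid point.  The default grid is
    -2..2 in steps of 0.01; ties in p (which saturates at the tails of the
    approximation) are broken toward the smaller A2 statistic.
    """
    if grid is None:
        grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)
    best = None
    for lam in grid:
        z = box_cox(y, float(lam))
        try:
            a2, p = anderson_darling(z)
        except ValueError:
            continue
        key = (p, -a2)
        if best is None or key > best[0]:
            best = (key, float(lam), a2, p)
    if best is None:
        raise ValueError("no usable Box-Cox exponent on the grid")
    return best[1], best[2], best[3]


def prefit_temp_term(T, y, form: str) -> tuple[TempTerm, dict]:
    """Least-squares pre-fit of ``y = a + b * term(T; T0)``.

    Estimates T0 (for saturating and quadratic forms) by nonlinear least
    squares, initializing the quadratic optimum at the y-weighted mean of
    T.  Returns the fitted :class:`TempTerm` and a dict with the
    intercept/slope and residual summary.
    """
    T = np.asarray(T, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(T).size < 3:
        raise ValueError("need at least 3 distinct temperatures")
    if form == "inverse_square":
        term = TempTerm("inverse_square")
        X = np.column_stack([np.ones_like(T), term(T)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return term, {"intercept": coef[0], "slope": coef[1], "rss": float(resid @ resid)}

    if form == "quadratic":
        w = np.abs(y)
        t0_init = float(np.sum(w * T) / np.sum(w)) if np.sum(w) > 0 else float(np.mean(T))
    elif form == "saturating":
        t0_init = float(np.median(T))
    else:
        raise ValueError(f"unknown temperature term {form!r}")

    def rss(t0):
        term = TempTerm(form, float(t0))
        X = np.column_stack([np.ones_like(T), term(T)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r), coef

    res = optimize.minimize_scalar(
        lambda t0: rss(t0)[0],
        bounds=(float(T.min()) - 30.0, float(T.max()) + 30.0),
        method="bounded",
    )
    t0 = float(res.x)
    # keep the initial value if the bounded search did not improve on it
    if rss(t0_init)[0] < res.fun:
        t0 = t0_init
    final_rss, coef = rss(t0)
    term = TempTerm(form, t0)
    return term, {"intercept": coef[0], "slope": coef[1], "rss": final_rss, "T0_init": t0_init}
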