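"""Maximum-likelihood fitting of the flight models, statsmodels-style.

:class:`FlightModel` couples a mean function (linear-with-temperature-term,
logistic, or power-law), an error family, and a per-female data table.
``fit()`` maximizes the likelihood by a multi-start Nelder-Mead search
followed by a quasi-Newton polish (shape parameters on the log scale) and
returns a :class:`FlightResults` carrying estimates, standard errors from
the inverse numerical Hessian, the maximized log-likelihood, AICc, and a
``summary()`` table.

Model selection follows two rules: candidate terms are added one at a
time in LASSO entry order (then single-term removals are attempted), with
support for each step expressed as ``exp(-0.5 * delta_AICc)`` relative to
the best model; the error family is the one whose fitted deviates show
the highest correlation between observed and expected cumulative
frequencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess

from .equations import ModelSpec, get_equation
from .errors import ErrorFamily, expected_cumfreq, get_family
from .transforms import TempTerm

__all__ = [
    "FlightModel",
    "FlightResults",
    "BuildTable",
    "aicc",
    "support",
    "incremental_build",
    "select_family",
]

log = logging.getLogger(__name__)


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def support(aicc_i: float, aicc_best: float) -> float:
    """Relative likelihood exp(-0.5 (AICc_i - AICc_best)), in (0, 1]."""
    if aicc_i < aicc_best:
        log.warning("support called with aicc_i < aicc_best; swapping")
        aicc_i, aicc_best = aicc_best, aicc_i
    return math.exp(-0.5 * (aicc_i - aicc_best))


# ---------------------------------------------------------------------------
# Mean functions


class LinearMean:
    """mu = p1 + sum coef_j x_j, optionally through a logistic link.

    The term named ``"T"`` is passed through the model's temperature
    transformation; when that transformation has a free optimum the
    parameter ``T0`` is appended to the parameter vector.
    """

    def __init__(self, terms, temp_term: TempTerm | None = None, logistic: bool = False):
        self.terms = tuple(terms)
        self.temp_term = temp_term
        self.logistic = logistic
        self.free_T0 = (
            temp_term is not None and temp_term.has_T0 and "T" in self.terms
        )
        self.param_names = ["p1"] + list(self.terms) + (["T0"] if self.free_T0 else [])

    def _design(self, df: pd.DataFrame, T0: float | None):
        cols = []
        for t in self.terms:
            if t == "T" and self.temp_term is not None:
                cols.append(self.temp_term(df["T"].to_numpy(dtype=float), T0))
            else:
                cols.append(df[t].to_numpy(dtype=float))
        if not cols:
            return np.empty((len(df), 0))
        return np.column_stack(cols)

    def __call__(self, theta, df: pd.DataFrame):
        theta = np.asarray(theta, dtype=float)
        T0 = float(theta[-1]) if self.free_T0 else None
        m = len(self.terms)
        lin = theta[0] + (self._design(df, T0) @ theta[1 : 1 + m] if m else 0.0)
        lin = np.broadcast_to(np.asarray(lin, dtype=float), (len(df),)).copy()
        return expit(lin) if self.logistic else lin

    def init_params(self, df: pd.DataFrame, y: np.ndarray) -> np.ndarray:
        T0 = self.temp_term.T0 if self.free_T0 else None
        X = np.column_stack([np.ones(len(df)), self._design(df, T0)])
        if self.logistic:
            # a few IRLS steps give an adequate logistic start
            beta = np.zeros(X.shape[1])
            for _ in range(25):
                p = expit(X @ beta)
                W = np.clip(p * (1 - p), 1e-6, None)
                z = X @ beta + (y - p) / W
                beta_new, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
                if np.max(np.abs(beta_new - beta)) < 1e-8:
                    beta = beta_new
                    break
                beta = beta_new
        else:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        theta = list(beta)
        if self.free_T0:
            theta.append(T0)
        return np.asarray(theta, dtype=float)

    # linear parameters are optimized on their natural scale
    def to_internal(self, theta):
        return np.asarray(theta, dtype=float).copy()

    def to_natural(self, theta):
        return np.asarray(theta, dtype=float).copy()


class PowerLawMean:
    """mu = p1 * prod_j x_j^{e_j}; p1 is optimized on the log scale."""

    def __init__(self, terms):
        self.terms = tuple(terms)
        self.param_names = ["p1"] + list(self.terms)
        self.free_T0 = False

    def __call__(self, theta, df: pd.DataFrame):
        theta = np.asarray(theta, dtype=float)
        if theta[0] <= 0:
            return np.full(len(df), -np.inf)
        logmu = np.full(len(df), math.log(theta[0]))
        for j, t in enumerate(self.terms):
            x = df[t].to_numpy(dtype=float)
            logmu = logmu + theta[1 + j] * np.log(x)
        return np.exp(logmu)

    def init_params(self, df: pd.DataFrame, y: np.ndarray) -> np.ndarray:
        mask = y > 0
        X = np.column_stack(
            [np.ones(int(mask.sum()))]
            + [np.log(df[t].to_numpy(dtype=float)[mask]) for t in self.terms]
        )
        beta, *_ = np.linalg.lstsq(X, np.log(y[mask]), rcond=None)
        return np.concatenate([[math.exp(beta[0])], beta[1:]])

    def to_internal(self, theta):
        theta = np.asarray(theta, dtype=float).copy()
        theta[0] = math.log(theta[0])
        return theta

    def to_natural(self, theta):
        theta = np.asarray(theta, dtype=float).copy()
        theta[0] = math.exp(theta[0])
        return theta


class Bernoulli(ErrorFamily):
    """Bernoulli likelihood on a logistic mean (flight propensity)."""

    def __init__(self):
        super().__init__(n_shape=0, name="bernoulli", multiplicative=False)

    def nll(self, y, mu, shape):
        mu = np.clip(np.asarray(mu, dtype=float), 1e-12, 1 - 1e-12)
        y = np.asarray(y, dtype=float)
        return -float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

    def sample(self, mu, shape, rng):
        return (rng.random(np.shape(mu)) < np.asarray(mu, dtype=float)).astype(float)


def _shape_name(family: ErrorFamily) -> str | None:
    if family.n_shape == 0:
        return None
    return "kappa" if family.name == "weibull" else "sigma2"


def build_mean(spec: ModelSpec):
    if spec.mean_kind == "power":
        return PowerLawMean(spec.terms)
    if spec.mean_kind == "logistic":
        return LinearMean(spec.terms, temp_term=spec.temp_term, logistic=True)
    if spec.mean_kind == "linear":
        return LinearMean(spec.terms, temp_term=spec.temp_term)
    raise ValueError(f"unknown mean kind {spec.mean_kind!r}")


def _get_family(name: str) -> ErrorFamily:
    if name == "bernoulli":
        return Bernoulli()
    return get_family(name)


# ---------------------------------------------------------------------------


class FlightModel:
    """A flight/cost model bound to data, fitted by maximum likelihood.

    Parameters
    ----------
    data : DataFrame
        One row per female; must contain the response column and all
        predictor columns named by the spec's terms.
    spec : ModelSpec
        Mean function + error family definition (see
        :mod:`budwormflight.equations`); use :meth:`from_equation` for the
        ten published equations.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.mean = build_mean(spec)
        self.family = _get_family(spec.family)
        cols = [spec.response] + [t for t in spec.terms if t != "T"]
        if "T" in spec.terms:
            cols.append("T")
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing columns {missing}")
        self.data = data.dropna(subset=cols).reset_index(drop=True)
        self.endog = self.data[spec.response].to_numpy(dtype=float)
        if self.family.multiplicative and np.any(self.endog <= 0):
            raise ValueError(
                f"multiplicative family {self.family.name!r} requires a positive response"
            )
        self.param_names = list(self.mean.param_names)
        sn = _shape_name(self.family)
        if sn:
            self.param_names.append(sn)
        self.k = len(self.param_names)
        self.nobs = len(self.data)

    @classmethod
    def from_equation(cls, eq_id: int, data: pd.DataFrame, terms=None, family=None):
        spec = get_equation(eq_id)
        if terms is not None:
            spec = spec.with_terms(terms)
        if family is not None:
            spec = spec.with_family(family)
        return cls(data, spec)

    # -- likelihood ---------------------------------------------------------

    def _split(self, theta_nat):
        nm = len(self.mean.param_names)
        mean_par = np.asarray(theta_nat[:nm], dtype=float)
        shape = float(theta_nat[nm]) if self.k > nm else None
        return mean_par, shape

    def nloglike(self, theta_nat) -> float:
        mean_par, shape = self._split(theta_nat)
        mu = self.mean(mean_par, self.data)
        if not np.all(np.isfinite(mu)):
            return np.inf
        if self.family.multiplicative and np.any(mu <= 0):
            return np.inf
        return self.family.nll(self.endog, mu, shape)

    def loglike(self, theta_nat) -> float:
        return -self.nloglike(theta_nat)

    def _nll_internal(self, theta_int) -> float:
        theta_nat = self._to_natural(theta_int)
        return self.nloglike(theta_nat)

    def _to_internal(self, theta_nat):
        nm = len(self.mean.param_names)
        out = np.concatenate(
            [self.mean.to_internal(theta_nat[:nm]), np.asarray(theta_nat[nm:], dtype=float)]
        )
        if self.k > nm:
            out[-1] = math.log(max(out[-1], 1e-12))  # shape on log scale
        return out

    def _to_natural(self, theta_int):
        nm = len(self.mean.param_names)
        out = np.concatenate(
            [self.mean.to_natural(theta_int[:nm]), np.asarray(theta_int[nm:], dtype=float)]
        )
        if self.k > nm:
            out[-1] = math.exp(out[-1])
        return out

    def start_params(self) -> np.ndarray:
        theta = list(self.mean.init_params(self.data, self.endog))
        if _shape_name(self.family):
            mu = self.mean(np.asarray(theta), self.data)
            if self.family.multiplicative:
                mu = np.where(mu > 0, mu, np.nanmedian(mu[mu > 0]) if np.any(mu > 0) else 1.0)
            dev = self.family.deviates(self.endog, mu)
            theta.append(self.family.init_shape(dev))
        return np.asarray(theta, dtype=float)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        start_params=None,
        n_starts: int = 5,
        seed: int = 0,
        maxiter: int | None = None,
    ) -> "FlightResults":
        """Maximize the likelihood; multi-start Nelder-Mead + BFGS polish."""
        start = np.asarray(
            self.start_params() if start_params is None else start_params, dtype=float
        )
        x0 = self._to_internal(start)
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(max(n_starts - 1, 0)):
            jitter = rng.normal(0.0, 0.1, size=x0.size) * (np.abs(x0) + 0.05)
            starts.append(x0 + jitter)
        if maxiter is None:
            maxiter = 400 * self.k

        best = None
        for s in starts:
            if not np.isfinite(self._nll_internal(s)):
                continue
            res = optimize.minimize(
                self._nll_internal,
                s,
                method="Nelder-Mead",
                options={"maxiter": maxiter, "fatol": 1e-10, "xatol": 1e-8},
            )
            res2 = optimize.minimize(self._nll_internal, res.x, method="BFGS")
            cand = res2 if res2.fun <= res.fun else res
            if best is None or cand.fun < best.fun:
                best = cand
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(
                f"fit failed for {self.spec.response!r}: no feasible starting point"
            )

        theta = self._to_natural(best.x)
        llf = -float(best.fun)

        bse, hess_pd = self._standard_errors(theta)
        return FlightResults(
            model=self,
            params=pd.Series(theta, index=self.param_names),
            bse=pd.Series(bse, index=self.param_names),
            llf=llf,
            converged=bool(np.isfinite(llf)),
            hess_pd=hess_pd,
        )

    def _standard_errors(self, theta_nat):
        try:
            H = approx_hess(np.asarray(theta_nat, dtype=float), self.nloglike)
            eig = np.linalg.eigvalsh(H)
            if np.any(eig <= 0):
                return np.full(self.k, np.nan), False
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.any(d < 0):
                return np.full(self.k, np.nan), False
            return np.sqrt(d), True
        except Exception:  # Hessian may fail near a boundary
            return np.full(self.k, np.nan), False


@dataclass
class FlightResults:
    """Container for one maximum-likelihood fit."""

    model: FlightModel
    params: pd.Series
    bse: pd.Series
    llf: float
    converged: bool
    hess_pd: bool

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k, self.nobs)

    @property
    def shape(self) -> float | None:
        sn = _shape_name(self.model.family)
        if sn is None:
            f = self.model.family
            return getattr(f, "fixed_kappa", None)
        return float(self.params[sn])

    def predict(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """Predicted mean on the fitted response scale."""
        df = self.model.data if data is None else data
        nm = len(self.model.mean.param_names)
        return self.model.mean(self.params.to_numpy()[:nm], df)

    def deviates(self) -> np.ndarray:
        """Fitted deviates: residuals or ratios depending on the family."""
        return self.model.family.deviates(self.model.endog, self.predict())

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"Flight model: {spec.label or spec.response}  (equation {spec.eq_id})",
            f"Family: {self.model.family.name}   N = {self.nobs}   k = {self.k}",
            f"logL = {self.llf:.3f}   AICc = {self.aicc:.1f}",
            f"{'parameter':>12} {'estimate':>12} {'SE':>10}",
        ]
        for name in self.params.index:
            se = self.bse[name]
            se_s = f"{se:.4g}" if np.isfinite(se) else "--"
            lines.append(f"{name:>12} {self.params[name]:>12.4g} {se_s:>10}")
        if not self.hess_pd:
            lines.append("warning: Hessian not positive definite; SEs not reported")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "equation": self.model.spec.eq_id,
            "response": self.model.spec.response,
            "family": self.model.family.name,
            "n": self.nobs,
            "k": self.k,
            "logL": self.llf,
            "AICc": self.aicc,
            "estimates": {k: float(v) for k, v in self.params.items()},
            "se": {k: (float(v) if np.isfinite(v) else None) for k, v in self.bse.items()},
            "hessian_pd": self.hess_pd,
        }

    # Monte-Carlo band / effect displays live in budwormflight.uncertainty;
    # exposed here for discoverability.
    def conf_band(self, grid_df, **kwargs):
        from .uncertainty import mc_confidence_band

        return mc_confidence_band(self, grid_df, **kwargs)

    def deviation_series(self, focal: str, **kwargs):
        from .uncertainty import deviation_series

        return deviation_series(self, focal, **kwargs)


# ---------------------------------------------------------------------------
# Incremental model building and family selection


@dataclass
class BuildTable:
    """Ordered record of the incremental AICc model-building steps."""

    rows: pd.DataFrame  # columns: step, AICc, support
    final: FlightResults

    def to_dict(self) -> dict:
        return {
            "steps": self.rows.to_dict(orient="records"),
            "final": self.final.to_dict(),
        }


_TIE_TOL = 1e-6


def incremental_build(
    data: pd.DataFrame,
    spec: ModelSpec,
    entry_order=None,
    seed: int = 0,
    n_starts: int = 3,
) -> BuildTable:
    """Build a model by adding terms in entry order, then trying removals.

    Starts from a null model (intercept and distribution parameter only),
    adds one candidate term per step in ``entry_order`` recording AICc,
    then attempts single-term removals from the full model and keeps the
    minimum-AICc model (ties within 1e-6 resolved toward the smaller
    model).  Supports are recomputed against the overall minimum so the
    final model's support is exactly 1.
    """
    order = list(entry_order if entry_order is not None else spec.terms)
    steps: list[tuple[str, float, FlightResults | None]] = []

    def _fit(terms):
        m = FlightModel(data, spec.with_terms(terms))
        return m.fit(seed=seed, n_starts=n_starts)

    try:
        res = _fit(())
        steps.append(("intercept", res.aicc, res))
    except Exception as e:  # pragma: no cover - null model rarely fails
        log.warning("null model failed: %s", e)
        steps.append(("intercept", np.nan, None))

    included: list[str] = []
    for term in order:
        included.append(term)
        try:
            res = _fit(tuple(included))
            steps.append((term, res.aicc, res))
        except Exception as e:
            log.warning("step +%s failed (%s); skipped", term, e)
            steps.append((f"{term} (failed)", np.nan, None))
            included.pop()

    full_terms = list(included)
    fitted = [s for s in steps if s[2] is not None]
    best_step = min(fitted, key=lambda s: s[1])
    final_res = steps[-1][2] if steps[-1][2] is not None else best_step[2]
    final_aicc = final_res.aicc

    # single-term removals from the full model
    if len(full_terms) > 1:
        removals = []
        for term in full_terms:
            reduced = tuple(t for t in full_terms if t != term)
            try:
                res = _fit(reduced)
                removals.append((term, res))
            except Exception as e:
                log.warning("removal of %s failed (%s); skipped", term, e)
        if removals:
            term, res = min(removals, key=lambda r: r[1].aicc)
            if res.aicc < final_aicc + _TIE_TOL:
                steps.append((f"{term} removed", res.aicc, res))
                final_res = res

    aiccs = np.array([s[1] for s in steps], dtype=float)
    best = np.nanmin(aiccs)
    # tie toward the smaller model: earlier rows have fewer terms except the
    # removal row, which is smaller than the full model preceding it
    rows = pd.DataFrame(
        {
            "step": [s[0] for s in steps],
            "AICc": aiccs,
            "support": [support(a, best) if np.isfinite(a) else np.nan for a in aiccs],
        }
    )
    candidates = [s for s in steps if s[2] is not None and s[1] <= best + _TIE_TOL]
    final_res = min(candidates, key=lambda s: (s[2].k, s[1]))[2]
    return BuildTable(rows=rows, final=final_res)


def select_family(
    data: pd.DataFrame, spec: ModelSpec, candidates=("normal", "lognormal", "weibull"),
    seed: int = 0,
) -> tuple[str, dict[str, float], dict[str, FlightResults]]:
    """Choose the deviate family by cumulative-frequency correlation.

    Fits the spec under each candidate family, computes the fitted
    deviates, and returns the family whose deviates correlate best with
    their expected cumulative frequencies, together with the per-family
    correlations and fitted results.  Multiplicative families are skipped
    (with a log message) when the response contains non-positive values.
    """
    y = data[spec.response].dropna().to_numpy(dtype=float)
    corrs: dict[str, float] = {}
    fits: dict[str, FlightResults] = {}
    for fam in candidates:
        family = _get_family(fam)
        if family.multiplicative and np.any(y <= 0):
            log.info("family %s skipped: response has non-positive values", fam)
            continue
        try:
            res = FlightModel(data, spec.with_family(fam)).fit(seed=seed)
        except Exception as e:
            log.warning("family %s failed to fit: %s", fam, e)
            continue
        dev = res.deviates()
        try:
            _, _, r = expected_cumfreq(family, dev, res.shape)
        except ValueError as e:
            log.warning("family %s cumulative-frequency check failed: %s", fam, e)
            continue
        corrs[fam] = r
        fits[fam] = res
    if not corrs:
        raise RuntimeError("no candidate family could be fitted")
    best = max(corrs, key=corrs.get)
    return best, corrs, fits
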