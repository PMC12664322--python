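"""Monte-Carlo confidence bands and relative-deviation effect displays.

The 95% regression band is built by randomizing parameter vectors around
the maximum-likelihood estimates (independent normal draws scaled by each
parameter's standard error), keeping the draws whose likelihood-ratio
chi-square against the best fit is non-significant, and taking the
pointwise envelope of the accepted mean curves.  Replicates are increased
adaptively until roughly 100 equally likely parameter sets are accepted.

Effect displays express each observation relative to the model prediction
with the focal predictor held at its mean, bin those relative deviations
over the focal predictor's range (14 or 15 equal-width classes), and
compare them with the predicted relative-effect curve.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["mc_confidence_band", "deviation_series", "mean_curve"]

log = logging.getLogger(__name__)


def mc_confidence_band(
    results,
    grid_df: pd.DataFrame,
    alpha: float = 0.05,
    reps: int = 1000,
    max_reps: int = 10000,
    target_accept: int = 100,
    seed: int = 0,
    truncate_at_zero: bool | None = None,
):
    """Pointwise Monte-Carlo confidence envelope for the mean curve.

    Parameters are drawn independently as Normal(estimate, SE); a draw is
    accepted when ``2 (logL_best - logL_draw) < chi2(k, 1 - alpha)`` with
    degrees of freedom equal to the number of parameters varied.  Returns
    a DataFrame with columns ``mean``, ``lower``, ``upper`` over the grid,
    plus acceptance bookkeeping in ``.attrs``.
    """
    model = results.model
    theta = results.params.to_numpy(dtype=float)
    se = results.bse.to_numpy(dtype=float)
    if not np.all(np.isfinite(se)):
        raise ValueError("confidence band requires finite standard errors")
    k = int(np.count_nonzero(se > 0))
    nm = len(model.mean.param_names)
    crit = stats.chi2.ppf(1.0 - alpha, df=max(k, 1))
    ll_best = results.llf
    rng = np.random.default_rng(seed)
    mean_curve_vals = model.mean(theta[:nm], grid_df)
    if truncate_at_zero is None:
        truncate_at_zero = model.family.multiplicative

    accepted = []
    total = 0
    batch = reps
    while total < max_reps:
        draws = theta[None, :] + rng.normal(size=(batch, theta.size)) * se[None, :]
        for d in draws:
            ll = -model.nloglike(d)
            if np.isfinite(ll) and 2.0 * (ll_best - ll) < crit:
                accepted.append(model.mean(d[:nm], grid_df))
        total += batch
        if len(accepted) >= target_accept:
            break
        batch = min(batch, max_reps - total)
        if batch <= 0:
            break
    if not accepted:
        raise RuntimeError(
            "no accepted parameter draws; increase alpha, reps, or check SEs"
        )
    if len(accepted) < target_accept:
        log.warning("only %d accepted draws after %d replicates", len(accepted), total)
    curves = np.vstack(accepted)
    lower = curves.min(axis=0)
    upper = curves.max(axis=0)
    mean = mean_curve_vals
    if truncate_at_zero:
        n_trunc = int(np.count_nonzero(lower < 0)) + int(np.count_nonzero(mean < 0))
        if n_trunc:
            log.info("truncating %d negative predicted means at 0", n_trunc)
        lower = np.maximum(lower, 0.0)
        mean = np.maximum(mean, 0.0)
        upper = np.maximum(upper, 0.0)
    out = pd.DataFrame({"mean": mean, "lower": lower, "upper": upper}, index=grid_df.index)
    out.attrs["n_accepted"] = len(accepted)
    out.attrs["n_draws"] = total
    out.attrs["alpha"] = alpha
    return out


def _covariate_means(model) -> dict:
    cols = set(t for t in model.spec.terms)
    if "T" in model.spec.terms:
        cols.add("T")
    return {c: float(model.data[c].mean()) for c in cols}


def deviation_series(results, focal: str, n_bins: int | None = None):
    """Binned relative deviations and the predicted relative-effect curve.

    For each individual i, ``Y'_i = Y_i / f(focal at its mean, others at
    their individual values)``; the Y' are averaged within equal-width
    classes of the focal predictor (15 classes when n >= 300, else 14).
    The predicted curve is ``f(focal varying, others at their means) /
    f(all at means)``.  Returns ``(classes_df, curve_df)``.
    """
    model = results.model
    if focal not in model.spec.terms:
        raise ValueError(f"{focal!r} is not a term of the fitted model")
    df = model.data
    n = len(df)
    if n_bins is None:
        n_bins = 15 if n >= 300 else 14
    nm = len(model.mean.param_names)
    theta = results.params.to_numpy(dtype=float)[:nm]

    at_mean_focal = df.copy()
    at_mean_focal[focal] = df[focal].mean()
    f_ref = model.mean(theta, at_mean_focal)
    if model.family.multiplicative and np.any(f_ref <= 0):
        raise ValueError("reference prediction non-positive under a multiplicative family")
    yprime = model.endog / f_ref

    x = df[focal].to_numpy(dtype=float)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        if not m.any():
            continue
        rows.append(
            {
                "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "mean_deviation": float(np.mean(yprime[m])),
                "n": int(m.sum()),
            }
        )
    classes = pd.DataFrame(rows)

    means = {c: df[c].mean() for c in df.columns if df[c].dtype.kind in "fi"}
    grid = pd.DataFrame({focal: np.linspace(x.min(), x.max(), 200)})
    for t in model.spec.terms:
        if t != focal:
            grid[t] = means[t]
    if "T" in model.spec.terms and "T" not in grid.columns:
        grid["T"] = means["T"]
    all_means = pd.DataFrame({c: [means[c]] for c in grid.columns})
    denom = float(model.mean(theta, all_means)[0])
    curve = pd.DataFrame(
        {focal: grid[focal], "relative_effect": model.mean(theta, grid) / denom}
    )
    return classes, curve


def mean_curve(results, T_grid, covariate_means: dict | None = None):
    """Predicted response against temperature at fixed covariate means.

    Negative predicted means under a multiplicative family are truncated
    at zero (count recorded in ``.attrs['n_truncated']``).
    """
    model = results.model
    if covariate_means is None:
        covariate_means = _covariate_means(model)
    grid = pd.DataFrame({"T": np.asarray(T_grid, dtype=float)})
    for t in model.spec.terms:
        if t != "T":
            grid[t] = covariate_means[t]
    nm = len(model.mean.param_names)
    mu = model.mean(results.params.to_numpy(dtype=float)[:nm], grid)
    n_trunc = 0
    if model.family.multiplicative:
        n_trunc = int(np.count_nonzero(mu < 0))
        mu = np.maximum(mu, 0.0)
    out = pd.DataFrame({"T": grid["T"], "mean": mu})
    out.attrs["n_truncated"] = n_trunc
    return out
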