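"""LASSO screening: ordering candidate predictors before model building.

For each response, the candidate pool is the six morphological traits
plus the pre-fitted temperature term and barometric pressure.  An L1
regularization path is computed on internally standardized predictors
from ``lambda_max`` (all coefficients zero) downward on a geometric grid;
the order in which predictors first acquire a nonzero coefficient is the
order in which they are later offered to the likelihood model builder.
A stopping point (minimum AICc along the path) is also reported, but only
the entry order drives downstream model building.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression, lasso_path

__all__ = ["ScreeningResult", "lasso_order"]

log = logging.getLogger(__name__)


@dataclass
class ScreeningResult:
    response: str
    candidates: list[str]
    entry_order: list[str]
    selected: list[str]
    dropped: list[str] = field(default_factory=list)
    separation_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "candidates": self.candidates,
            "entry_order": self.entry_order,
            "selected": self.selected,
            "dropped": self.dropped,
            "separation_flag": self.separation_flag,
        }


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = np.zeros_like(X)
    Z[:, keep] = (X[:, keep] - mu[keep]) / sd[keep]
    return Z, keep


def _gaussian_aicc(y, yhat, k, n):
    rss = float(np.sum((y - yhat) ** 2))
    if rss <= 0:
        return -np.inf
    ll = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)
    if n - k - 1 <= 0:
        return np.inf
    return -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _binomial_aicc(y, p, k, n):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    if n - k - 1 <= 0:
        return np.inf
    return -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def lasso_order(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    family: str = "gaussian",
    response: str = "",
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> ScreeningResult:
    """Order predictors by first entry along an L1 regularization path.

    ``family`` is ``"gaussian"`` for continuous responses or
    ``"binomial"`` for 0/1 responses (penalized logistic regression).
    Constant predictors are dropped with a warning.  Perfect separation in
    the binomial case is flagged and the path truncated at that point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than candidate predictors")
    if len(names) != p:
        raise ValueError("names must match the number of predictor columns")

    Z, keep = _standardize(X)
    dropped = [nm for nm, k in zip(names, keep) if not k]
    if dropped:
        log.warning("dropping constant predictors: %s", dropped)
    active_names = [nm for nm, k in zip(names, keep) if k]
    Z = Z[:, keep]

    if family == "gaussian":
        yc = y - y.mean()
        lam_max = np.max(np.abs(Z.T @ yc)) / n
        alphas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
        _, coefs, _ = lasso_path(Z, yc, alphas=alphas, max_iter=5000)
        entry_idx = _first_entry(coefs)
        aiccs = []
        for j in range(len(alphas)):
            b = coefs[:, j]
            yhat = Z @ b + y.mean()
            k = int(np.count_nonzero(b)) + 1  # + intercept
            aiccs.append(_gaussian_aicc(y, yhat, k + 1, n))  # + variance
        best_j = int(np.argmin(aiccs))
        selected_mask = coefs[:, best_j] != 0
        separation = False
    elif family == "binomial":
        ybin = y.astype(int)
        if ybin.min() == ybin.max():
            raise ValueError("binomial response is constant")
        pbar = ybin.mean()
        lam_max = np.max(np.abs(Z.T @ (ybin - pbar))) / n
        alphas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
        coefs = np.zeros((Z.shape[1], len(alphas)))
        aiccs = np.full(len(alphas), np.inf)
        separation = False
        for j, lam in enumerate(alphas):
            clf = LogisticRegression(
                penalty="l1", C=1.0 / (n * lam), solver="liblinear", max_iter=500, tol=1e-8
            )
            clf.fit(Z, ybin)
            coefs[:, j] = clf.coef_[0]
            prob = clf.predict_proba(Z)[:, 1]
            if np.max(np.abs(clf.coef_)) > 50:
                # coefficients diverging: (quasi-)separation; truncate path
                separation = True
                coefs = coefs[:, : j + 1]
                aiccs = aiccs[: j + 1]
                log.warning("separation detected on the binomial path; truncating")
                break
            k = int(np.count_nonzero(clf.coef_[0])) + 1
            aiccs[j] = _binomial_aicc(ybin, prob, k, n)
        entry_idx = _first_entry(coefs)
        best_j = int(np.argmin(aiccs))
        selected_mask = coefs[:, best_j] != 0
    else:
        raise ValueError(f"unknown family {family!r}")

    order = [active_names[i] for i in entry_idx]
    selected = [nm for nm, m in zip(active_names, selected_mask) if m]
    return ScreeningResult(
        response=response,
        candidates=list(names),
        entry_order=order,
        selected=selected,
        dropped=dropped,
        separation_flag=separation,
    )


def _first_entry(coefs: np.ndarray) -> list[int]:
    """Indices of predictors ordered by first nonzero coefficient on the path."""
    p, m = coefs.shape
    first = np.full(p, np.inf)
    for i in range(p):
        nz = np.nonzero(np.abs(coefs[i]) > 1e-12)[0]
        if nz.size:
            first[i] = nz[0]
    order = [int(i) for i in np.argsort(first, kind="stable") if np.isfinite(first[i])]
    return order
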