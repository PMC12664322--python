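"""Decomposition of flight mass loss into water loss and fuel use.

A female's mass loss over the test, ``Wloss = Wb - Wa``, mixes
desiccation and fuel (lipid + carbohydrate) consumption.  The two are
separated through the dry-mass proportion: the final proportion
``Pd = Wd / Wa`` is regressed on temperature, flown distance
(``D' = ln(D + 1)`` for this regression) and final mass ``Wa`` with a
multiplicative mean-one lognormal deviate,

    Pd = (p1 + p2 T + p3 D' + p4 Wa) * delta.

Setting ``T = 0`` and ``D = 0`` in the fitted mean while keeping each
female's own deviate ``delta_i`` back-calculates her initial dry
proportion ``Pi = delta_i (p1 + p4 Wa)``; water lost is then
``Wwater = Wa (Pd - Pi)`` (clamped to 0.05 mg when non-positive) and fuel
used is the remainder ``Wfuel = Wb - Wa - Wwater``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equations import ModelSpec
from .models import FlightModel, FlightResults

__all__ = [
    "WATER_CLAMP_MG",
    "FUEL_SCREEN_OFFSET",
    "DryFractionModel",
    "dprime",
    "fit_dry_fraction",
    "initial_dry_fraction",
    "water_and_fuel",
    "water_budget_table",
]

log = logging.getLogger(__name__)

#: non-positive water-loss estimates are set to this value (mg)
WATER_CLAMP_MG = 0.05
#: offset added to all fuel masses before LASSO screening only
FUEL_SCREEN_OFFSET = 0.18


def dprime(D, convention: str = "cost"):
    """Distance transform D'.

    ``convention="cost"`` gives ``ln(D + e)`` (so D' = 1 at D = 0), used in
    the cost power laws; ``convention="pd"`` gives ``ln(D + 1)`` (so D' = 0
    at D = 0), used only in the dry-fraction regression.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("distance must be non-negative")
    if convention == "cost":
        return np.log(D + math.e)
    if convention == "pd":
        return np.log1p(D)
    raise ValueError(f"unknown D' convention {convention!r}")


@dataclass
class DryFractionModel:
    """Fitted Pd regression with per-individual deviate multipliers."""

    results: FlightResults
    delta_i: pd.Series  # Pd_i / fitted mean, one per individual

    @property
    def intercept(self) -> float:
        return float(self.results.params["p1"])

    @property
    def wa_coef(self) -> float:
        return float(self.results.params["Wa"])


_PD_SPEC = ModelSpec(
    eq_id=0,
    response="Pd",
    mean_kind="linear",
    terms=("T", "Dprime_pd", "Wa"),
    family="lognormal",
    label="final dry-mass proportion",
)


def fit_dry_fraction(df: pd.DataFrame, seed: int = 0) -> DryFractionModel:
    """ML fit of the dry-fraction regression.

    ``df`` needs columns T, distance_km, Wa, Pd.  Non-flyers enter with
    distance 0.  Returns the fitted model and each individual's deviate
    ``delta_i`` (sample mean close to 1 by the mean-one construction).
    """
    work = df.copy()
    needed = {"T", "Wa", "Pd"}
    if not needed.issubset(work.columns):
        raise ValueError(f"need columns {sorted(needed)}")
    if len(work) < 20:
        raise ValueError("need at least 20 individuals to fit the dry-fraction model")
    if np.any((work["Pd"] <= 0) | (work["Pd"] >= 1)):
        raise ValueError("Pd must lie strictly in (0, 1)")
    D = work["distance_km"].fillna(0.0) if "distance_km" in work else 0.0
    work["Dprime_pd"] = dprime(np.asarray(D, dtype=float), convention="pd")
    res = FlightModel(work, _PD_SPEC).fit(seed=seed)
    mu = res.predict(work)
    delta = pd.Series(work["Pd"].to_numpy(dtype=float) / mu, index=df.index, name="delta_i")
    return DryFractionModel(results=res, delta_i=delta)


def initial_dry_fraction(delta_i, Wa, model: DryFractionModel):
    """Back-calculate each female's initial dry proportion Pi.

    Pi = delta_i * (p1 + p4 * Wa), i.e. the fitted mean at T = 0 degC and
    D = 0 km scaled by the female's own deviate.  Values outside (0, 1)
    are retained but trigger a warning.
    """
    Wa = np.asarray(Wa, dtype=float)
    if np.any(Wa < 0):
        raise ValueError("Wa must be positive")
    pi = np.asarray(delta_i, dtype=float) * (model.intercept + model.wa_coef * Wa)
    bad = np.count_nonzero((pi <= 0) | (pi >= 1))
    if bad:
        log.warning("%d back-calculated Pi values fall outside (0, 1); retained", bad)
    return pi


def water_and_fuel(Wb, Wa, Pd, Pi):
    """Water lost and fuel used per female.

    Wwater = Wa (Pd - Pi), clamped to 0.05 mg when non-positive (count
    logged); Wfuel = Wb - Wa - Wwater, negatives retained but counted.
    Returns ``(Wwater, Wfuel, clamped_mask, negative_fuel_mask)``.
    """
    Wb = np.asarray(Wb, dtype=float)
    Wa = np.asarray(Wa, dtype=float)
    if np.any(Wa > Wb):
        log.warning(
            "%d females gained mass during the test (Wa > Wb)",
            int(np.count_nonzero(Wa > Wb)),
        )
    wwater = Wa * (np.asarray(Pd, dtype=float) - np.asarray(Pi, dtype=float))
    clamped = wwater <= 0
    if clamped.any():
        log.info("clamping %d non-positive water-loss values to %.2f mg",
                 int(clamped.sum()), WATER_CLAMP_MG)
    wwater = np.where(clamped, WATER_CLAMP_MG, wwater)
    wfuel = Wb - Wa - wwater
    neg = wfuel < 0
    if neg.any():
        log.info("%d negative fuel-use values retained", int(neg.sum()))
    return wwater, wfuel, clamped, neg


def water_budget_table(df: pd.DataFrame, seed: int = 0) -> tuple[pd.DataFrame, DryFractionModel]:
    """Run the full decomposition, augmenting the per-female table.

    Adds Pd (if absent), Pi, Wwater, Wfuel and the clamp/negative flags.
    Requires columns Wb, Wa, Wd, T and (optionally) distance_km.
    """
    out = df.copy()
    if "Pd" not in out.columns:
        out["Pd"] = out["Wd"] / out["Wa"]
    model = fit_dry_fraction(out, seed=seed)
    out["delta_i"] = model.delta_i
    out["Pi"] = initial_dry_fraction(out["delta_i"], out["Wa"], model)
    wwater, wfuel, clamped, neg = water_and_fuel(out["Wb"], out["Wa"], out["Pd"], out["Pi"])
    out["Wwater"] = wwater
    out["Wfuel"] = wfuel
    out["water_clamped"] = clamped
    out["fuel_negative"] = neg
    return out, model
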