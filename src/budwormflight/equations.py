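"""Registry of the ten flight performance and cost equations.

Flight performance (fitted to one row per female, flyers only except
propensity):

1.  propensity   P = logistic(p1 + p_T*T + p_Stot*Stot + p_Wb*Wb), Bernoulli
2.  onset        psi' = (p1 + p_T/T^2) * xi,                Weibull
3.  wingbeat     nu   = (p1 + p_T*T/(T0+T) + p_La*La) * xi, Weibull
4.  speed        log10(eta) = p1 + p_T*(T-T0)^2 + p_La*La + eps, normal
5.  duration     delta = (p1 + p_T*(T-T0)^2 + p_tau*tau_t + p_S*Stot
                          + p_Ap*Ap + p_om*omega_tot) * xi, exponential
6.  distance     phi  = (p1 + p_T*(T-T0)^2 + p_La*La + p_Ap*Ap) * xi, Weibull

Flight costs (power laws; D' = ln(D + e) so D' = 1 at D = 0):

7.  mass loss    Wloss  = p1 * T^a * Wb^b * La^c * xi,      Weibull
8.  water loss   Wwater = p1 * T^a * D'^b * Wb^c * La^d * xi, Weibull
9.  fuel use     Wfuel  = p1 * T^a * Wb^b * La^c * xi,      Weibull
10. lipids left  Wlipids = p1 * Wb^b * delta,               lognormal

Published estimates ship with each equation; they are the defaults the
synthetic-data generator simulates from, and the anchor points for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .transforms import TempTerm

__all__ = ["ModelSpec", "EQUATIONS", "get_equation", "ONSET_BOXCOX_LAMBDA"]

#: Box-Cox exponent normalizing flight onset time (psi' = (psi^0.09 - 1)/0.09)
ONSET_BOXCOX_LAMBDA = 0.09


@dataclass(frozen=True)
class ModelSpec:
    """A mean function + error family definition for one response."""

    eq_id: int
    response: str  # column fitted (native or transformed scale)
    mean_kind: str  # "linear" | "logistic" | "power"
    terms: tuple[str, ...]  # predictor terms in the order they enter
    family: str  # normal | lognormal | weibull | exponential | bernoulli
    temp_term: TempTerm | None = None
    params: dict = field(default_factory=dict)  # published estimates
    se: dict = field(default_factory=dict)  # published standard errors
    N: int | None = None  # paper sample size
    label: str = ""

    def with_terms(self, terms) -> "ModelSpec":
        return replace(self, terms=tuple(terms))

    def with_family(self, family: str) -> "ModelSpec":
        return replace(self, family=family)


EQUATIONS: dict[int, ModelSpec] = {
    1: ModelSpec(
        eq_id=1,
        response="flew",
        mean_kind="logistic",
        terms=("T", "Stot", "Wb"),
        family="bernoulli",
        params={"p1": -8.523, "T": 0.307, "Stot": 0.064, "Wb": -0.090},
        se={"p1": 1.406, "T": 0.039, "Stot": 0.017, "Wb": 0.032},
        N=379,
        label="flight propensity",
    ),
    2: ModelSpec(
        eq_id=2,
        response="psi_prime",
        mean_kind="linear",
        terms=("T",),
        family="weibull",
        temp_term=TempTerm("inverse_square"),
        params={"p1": 0.005, "T": 4.465, "kappa": 0.578},
        se={"p1": 0.002, "T": 0.978, "kappa": 0.025},
        N=295,
        label="flight onset time (Box-Cox scale)",
    ),
    3: ModelSpec(
        eq_id=3,
        response="wingbeat_hz",
        mean_kind="linear",
        terms=("T", "La"),
        family="weibull",
        temp_term=TempTerm("saturating", 23.242),
        params={"p1": 4.178, "T": 77.331, "La": -0.446, "T0": 23.242, "kappa": 10.908},
        se={"p1": 5.065, "T": 3.813, "La": 0.241, "T0": 7.337, "kappa": 0.629},
        N=215,
        label="wingbeat frequency",
    ),
    4: ModelSpec(
        eq_id=4,
        response="log10_speed",
        mean_kind="linear",
        terms=("T", "La"),
        family="normal",
        temp_term=TempTerm("quadratic", 27.117),
        params={"p1": -1.213, "T": -0.001, "La": 0.077, "T0": 27.117, "sigma2": 0.035},
        se={"p1": 0.124, "T": 0.0001, "La": 0.013, "T0": 1.023, "sigma2": 0.003},
        N=282,
        label="flight speed (log10 m/s)",
    ),
    5: ModelSpec(
        eq_id=5,
        response="duration_h",
        mean_kind="linear",
        terms=("T", "tau_t", "Stot", "Ap", "omega_tot"),
        family="exponential",
        temp_term=TempTerm("quadratic", 23.718),
        params={
            "p1": -24.197,
            "T": -0.012,
            "tau_t": -29.721,
            "Stot": 0.016,
            "Ap": 0.281,
            "omega_tot": -9.754,
            "T0": 23.718,
        },
        se={
            "p1": 1.003,
            "T": 0.001,
            "tau_t": 9.141,
            "Stot": 0.004,
            "Ap": 0.008,
            "omega_tot": 1.650,
            "T0": 0.271,
        },
        N=295,
        label="flight duration (h)",
    ),
    6: ModelSpec(
        eq_id=6,
        response="distance_km",
        mean_kind="linear",
        terms=("T", "La", "Ap"),
        family="weibull",
        temp_term=TempTerm("quadratic", 23.551),
        params={
            "p1": -9.912,
            "T": -0.024,
            "La": 0.382,
            "Ap": 0.109,
            "T0": 23.551,
            "kappa": 0.691,
        },
        se={"p1": 0.796, "T": 0.003, "La": 0.082, "Ap": 0.007, "T0": 0.255, "kappa": 0.034},
        N=295,
        label="distance flown (km)",
    ),
    7: ModelSpec(
        eq_id=7,
        response="Wloss",
        mean_kind="power",
        terms=("T", "Wb", "La"),
        family="weibull",
        params={"p1": 0.002, "T": 0.992, "Wb": 0.442, "La": 1.260, "kappa": 2.703},
        se={"p1": 0.002, "T": 0.069, "Wb": 0.165, "La": 0.575, "kappa": 0.134},
        N=219,
        label="body mass loss (mg)",
    ),
    8: ModelSpec(
        eq_id=8,
        response="Wwater",
        mean_kind="power",
        terms=("T", "Dprime", "Wb", "La"),
        family="weibull",
        params={
            "p1": 0.0003,
            "T": 1.178,
            "Dprime": -0.963,
            "Wb": 0.916,
            "La": 0.485,
            "kappa": 7.223,
        },
        se={"p1": 0.0001, "T": 0.030, "Dprime": 0.038, "Wb": 0.054, "La": 0.204, "kappa": 0.418},
        N=214,
        label="water loss (mg)",
    ),
    9: ModelSpec(
        eq_id=9,
        response="Wfuel",
        mean_kind="power",
        terms=("T", "Wb", "La"),
        family="weibull",
        params={"p1": 0.0007, "T": 1.037, "Wb": 0.328, "La": 1.687, "kappa": 2.230},
        se={"p1": 0.0008, "T": 0.085, "Wb": 0.206, "La": 0.718, "kappa": 0.115},
        N=214,
        label="fuel use (mg)",
    ),
    10: ModelSpec(
        eq_id=10,
        response="Wlipids",
        mean_kind="power",
        terms=("Wb",),
        family="lognormal",
        params={"p1": 0.086, "Wb": 1.051, "sigma2": 0.022},
        se={"p1": 0.009, "Wb": 0.030, "sigma2": 0.0001},
        N=216,
        label="remaining lipid mass (mg)",
    ),
}


def get_equation(eq_id: int) -> ModelSpec:
    try:
        return EQUATIONS[eq_id]
    except KeyError:
        raise ValueError(f"equation id must be 1-10, got {eq_id}")
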