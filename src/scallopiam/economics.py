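"""Annual bioeconomic layer of the fishery model.

A two-step decision is made at the start of each model year. The management
step projects the stock one year forward at F_ABC to set the allowable
biological catch Q_ABC and the corresponding fleet days-at-sea cap DAS_max.
The fleet step then chooses days at sea DAS to maximize fleet profit
(gross revenue minus operating cost) subject to four constraints: marginal
cost not exceeding marginal crew income, landings net of exports not
exceeding national demand, catch not exceeding Q_ABC, and DAS not exceeding
DAS_max.

Production is Cobb-Douglas in stock biomass and effort,
Q = exp(A) BIO^alpha DAS^beta (A = -9.95 on the log scale), fitted to
2000-2009 landings/biomass/effort; cost is C = w DAS, equivalently
w (Q / (exp(A) BIO^alpha))^(1/beta). The fleet is a price taker, so
marginal revenue equals the landings-weighted mean ex-vessel price.
Demand evolves with own-price (-0.368) and income (1.83) elasticities.
All dollars are 2011 USD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "EconParams",
    "EconState",
    "AnnualDecision",
    "production_q",
    "total_cost",
    "marginal_cost",
    "marginal_crew_income",
    "marginal_revenue",
    "mean_price",
    "update_demand",
    "update_prices",
    "update_cost_per_day",
    "das_max",
    "das_to_F",
    "optimize_effort",
]

MARKET_CLASSES = ("U10", "11-20", "21-30", "31-40")
GRID_POINTS = 1000
BIND_RTOL = 1e-6


@dataclass(frozen=True)
class EconParams:
    """Socioeconomic parameters (Table-scale constants, 2011 USD)."""

    e_p: float = -0.368        # own-price elasticity of demand
    e_i: float = 1.83          # income elasticity of demand
    GRT: float = 166.2         # tons, average vessel tonnage (bookkeeping)
    alpha: float = 1.195       # production-function biomass exponent
    beta: float = 0.449        # production-function effort exponent
    A: float = -9.95           # production-function log-scale intercept
    CREW: int = 7
    crew_share: float = 0.52   # crew share of net revenue
    fee: float = 0.05          # landings fee fraction
    R_fuel: float = 1.1        # % yr-1, fuel price growth
    fuel_share: float = 0.3    # fuel share of daily operating cost
    F_msy: float = 0.38        # yr-1
    F_abc: float = 0.32        # yr-1
    # price-model surrogate: ln P_i = c_i + th_ip ln IP + th_pcdi ln PCDI
    theta_ip: float = 0.3
    theta_pcdi: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1): diminishing returns to effort")
        if self.e_p >= 0 or self.e_i <= 0:
            raise ValueError("price elasticity must be negative, income positive")


@dataclass
class EconState:
    """Evolving market state: prices, demand, income, and cost drivers."""

    prices: dict               # $ lb-1 per market class
    import_price: float        # $ lb-1
    pcdi: float                # $ per-capita disposable income
    demand: float              # lb
    fuel: float                # $ gal-1
    w: float                   # $ d-1, cost per day at sea
    exports: float             # lb
    shares: dict = field(default_factory=dict)   # last landings split by class
    price_intercepts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.demand <= 0:
            raise ValueError("demand must be positive")
        if any(v <= 0 for v in self.prices.values()):
            raise ValueError("prices must be positive")


@dataclass
class AnnualDecision:
    """Management limits, fleet optimum and its margins for one year."""

    Q_abc: float               # lb
    DAS_max: float             # d
    DAS: float                 # d
    Q: float                   # lb
    F_t: float                 # yr-1
    gross_revenue: float       # $
    cost: float                # $
    profit: float              # $
    MC: float                  # $ lb-1
    MCI: float
    MR: float
    binding: dict = field(default_factory=dict)
    feasible: bool = True


# ---------------------------------------------------------------------------
# production and cost

def production_q(BIO: float, DAS: float, p: EconParams) -> float:
    """Cobb-Douglas landings Q = exp(A) BIO^alpha DAS^beta (lb; BIO in lb, DAS in d)."""
    if BIO <= 0:
        raise ValueError("biomass must be positive")
    if DAS < 0:
        raise ValueError("days at sea must be non-negative")
    if DAS == 0:
        return 0.0
    return math.exp(p.A) * BIO ** p.alpha * DAS ** p.beta


def total_cost(Q: float, BIO: float, w: float, p: EconParams) -> float:
    """Operating cost C = w (Q / (exp(A) BIO^alpha))^(1/beta), dollars."""
    if Q < 0 or BIO <= 0:
        raise ValueError("Q must be non-negative and BIO positive")
    if Q == 0:
        return 0.0
    return w * (Q / (math.exp(p.A) * BIO ** p.alpha)) ** (1.0 / p.beta)


def marginal_cost(Q: float, BIO: float, w: float, p: EconParams) -> float:
    """MC = dC/dQ = (w/beta) (1/(exp(A) BIO^alpha))^(1/beta) Q^((1-beta)/beta)."""
    if Q < 0 or BIO <= 0:
        raise ValueError("Q must be non-negative and BIO positive")
    if Q == 0:
        return 0.0
    scale = (1.0 / (math.exp(p.A) * BIO ** p.alpha)) ** (1.0 / p.beta)
    return w / p.beta * scale * Q ** ((1.0 - p.beta) / p.beta)


def marginal_crew_income(P_bar: float, MC: float, p: EconParams) -> float:
    """MCI = (P - fee*P) * crew_share - MC (marginal crew share of revenue)."""
    if P_bar <= 0:
        raise ValueError("mean price must be positive")
    return (P_bar - p.fee * P_bar) * p.crew_share - MC


def marginal_revenue(P_bar: float) -> float:
    """Price-taker assumption: MR equals the mean ex-vessel price."""
    if P_bar <= 0:
        raise ValueError("mean price must be positive")
    return P_bar


def mean_price(prices: dict, shares: dict) -> float:
    """Landings-weighted mean price over market classes."""
    tot = sum(shares.get(c, 0.0) for c in MARKET_CLASSES)
    if tot <= 0:
        return float(np.mean([prices[c] for c in MARKET_CLASSES]))
    return sum(prices[c] * shares.get(c, 0.0) for c in MARKET_CLASSES) / tot


# ---------------------------------------------------------------------------
# market evolution

def update_demand(D_prev: float, r_p: float, r_i: float, p: EconParams) -> float:
    """Demand growth D_t = D_{t-1}(1 + e_p r_p + e_i r_i)."""
    if D_prev <= 0:
        raise ValueError("previous demand must be positive")
    r_d = p.e_p * r_p + p.e_i * r_i
    if r_d <= -1.0:
        raise RuntimeError(f"demand collapse: growth rate {r_d:.3f} <= -1")
    return D_prev * (1.0 + r_d)


def calibrate_price_intercepts(prices0: dict, ip0: float, pcdi0: float,
                               p: EconParams) -> dict:
    """Intercepts c_i such that the price model reproduces year-2000 prices."""
    return {c: math.log(prices0[c]) - p.theta_ip * math.log(ip0)
            - p.theta_pcdi * math.log(pcdi0) for c in MARKET_CLASSES}


def update_prices(econ: EconState, p: EconParams) -> dict:
    """Surrogate log-linear price model driven by import price and income.

    ln P_i = c_i + theta_ip ln IP_t + theta_pcdi ln PCDI_t, with the
    intercepts calibrated to the year-2000 printed prices.
    """
    if econ.import_price <= 0 or econ.pcdi <= 0:
        raise ValueError("price drivers must be positive")
    return {c: math.exp(econ.price_intercepts[c]
                        + p.theta_ip * math.log(econ.import_price)
                        + p.theta_pcdi * math.log(econ.pcdi))
            for c in MARKET_CLASSES}


def update_cost_per_day(w0: float, fuel_t: float, fuel0: float,
                        p: EconParams) -> float:
    """Daily cost w_t = w0 (1 - fuel_share + fuel_share * FUEL_t / FUEL_0)."""
    return w0 * (1.0 - p.fuel_share + p.fuel_share * fuel_t / fuel0)


# ---------------------------------------------------------------------------
# decision step

def das_max(Q_abc: float, BIO: float, p: EconParams) -> float:
    """Effort cap: days at sea whose production just reaches Q_ABC."""
    if Q_abc < 0:
        raise ValueError("Q_ABC must be non-negative")
    if Q_abc == 0:
        return 0.0
    return (Q_abc / (math.exp(p.A) * BIO ** p.alpha)) ** (1.0 / p.beta)


def das_to_F(DAS: float, F_das: float) -> float:
    """Fleet fishing mortality F_t = DAS * F_das (F_das calibrated at init)."""
    if DAS < 0:
        raise ValueError("DAS must be non-negative")
    return DAS * F_das


def calibrate_f_das(land0: float, bio0: float, das0: float) -> float:
    """Per-day fishing mortality from year-2000 landings, biomass and effort.

    F0 = -ln(1 - LAND0/BIO0) is the annual rate removing the observed
    landings fraction; F_das = F0 / DAS0.
    """
    frac = land0 / bio0
    if not 0 < frac < 1:
        raise ValueError("initial landings must be a fraction of biomass")
    return -math.log(1.0 - frac) / das0


def optimize_effort(Q_abc: float, DAS_cap: float, econ: EconState, BIO: float,
                    p: EconParams) -> AnnualDecision:
    """Profit-maximizing DAS on [0, DAS_max] under the four constraints.

    Grid search (1000 points) with bounded scalar refinement around the best
    cell; ties break toward smaller DAS. Constraints: MC <= MCI,
    Q - exports <= D, Q <= Q_ABC, DAS <= DAS_max. Returns a zero-effort
    decision flagged infeasible when nothing satisfies them.
    """
    if Q_abc < 0 or DAS_cap < 0:
        raise ValueError("limits must be non-negative")
    P_bar = mean_price(econ.prices, econ.shares)

    def q_of(das: float) -> float:
        return production_q(BIO, das, p) if das > 0 else 0.0

    def feasible(das: float) -> bool:
        q = q_of(das)
        if das > DAS_cap * (1 + BIND_RTOL) or q > Q_abc * (1 + BIND_RTOL) + 1e-9:
            return False
        if q - econ.exports > econ.demand * (1 + BIND_RTOL):
            return False
        mc = marginal_cost(q, BIO, econ.w, p)
        return mc <= marginal_crew_income(P_bar, mc, p) + BIND_RTOL * P_bar

    def profit(das: float) -> float:
        return P_bar * q_of(das) - econ.w * das

    grid = np.linspace(0.0, DAS_cap, GRID_POINTS)
    feas = np.array([feasible(d) for d in grid])
    if not feas.any():
        return AnnualDecision(Q_abc=Q_abc, DAS_max=DAS_cap, DAS=0.0, Q=0.0,
                              F_t=0.0, gross_revenue=0.0, cost=0.0, profit=0.0,
                              MC=0.0, MCI=marginal_crew_income(P_bar, 0.0, p),
                              MR=P_bar, feasible=False)
    profits = np.array([profit(d) if ok else -np.inf for d, ok in zip(grid, feas)])
    best = int(np.argmax(profits))          # argmax takes the first (smallest DAS) tie

    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, GRID_POINTS - 1)]
    if hi > lo:
        res = minimize_scalar(lambda d: -profit(d) if feasible(d) else 1e300,
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6 * max(DAS_cap, 1.0)})
        das_star = float(res.x) if (feasible(res.x)
                                    and -res.fun >= profits[best]) else float(grid[best])
    else:
        das_star = float(grid[best])

    q = q_of(das_star)
    mc = marginal_cost(q, BIO, econ.w, p)
    mci = marginal_crew_income(P_bar, mc, p)
    binding = {
        "DAS_max": das_star >= DAS_cap * (1 - BIND_RTOL) and DAS_cap > 0,
        "Q_abc": q >= Q_abc * (1 - BIND_RTOL) and Q_abc > 0,
        "demand": (q - econ.exports) >= econ.demand * (1 - BIND_RTOL),
        "MC_MCI": mc >= mci - BIND_RTOL * max(P_bar, 1.0),
    }
    return AnnualDecision(Q_abc=Q_abc, DAS_max=DAS_cap, DAS=das_star, Q=q,
                          F_t=0.0, gross_revenue=P_bar * q,
                          cost=econ.w * das_star,
                          profit=P_bar * q - econ.w * das_star,
                          MC=mc, MCI=mci, MR=P_bar, binding=binding)
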