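"""Bioeconomic layer: production/cost calculus, margins, demand, price
surrogate, effort optimization against brute force, parameter recovery."""

import math

import numpy as np
import pytest

from scallopiam.defaults import ECON_DEFAULTS, ECON_INITIAL
from scallopiam.economics import (EconParams, EconState,
                                  calibrate_f_das,
                                  calibrate_price_intercepts, das_max,
                                  das_to_F, marginal_cost,
                                  marginal_crew_income, marginal_revenue,
                                  mean_price, optimize_effort, production_q,
                                  total_cost, update_cost_per_day,
                                  update_demand, update_prices)

P = ECON_DEFAULTS
EI = ECON_INITIAL


def default_state(**kw):
    s = dict(prices=dict(EI["prices0"]), import_price=EI["IP0"],
             pcdi=EI["PCDI0"], demand=EI["D0_lb"], fuel=EI["FUEL0"],
             w=EI["w0"], exports=EI["exports_lb"], shares=dict(EI["shares0"]))
    s.update(kw)
    st = EconState(**s)
    st.price_intercepts = calibrate_price_intercepts(
        st.prices, st.import_price, st.pcdi, P)
    return st


# ---------------------------------------------------------------------------
# production and cost


def test_production_reproduces_year_2000_landings():
    """Cobb-Douglas at the printed year-2000 biomass and effort gives the
    printed landings within 2% (the log-scale reading of the intercept)."""
    q = production_q(EI["BIO0_lb"], EI["DAS0"], P)
    assert q == pytest.approx(EI["LAND0_lb"], rel=0.02)
    assert q == pytest.approx(3.18e7, rel=0.01)


def test_production_power_law_scalings():
    q1 = production_q(1e8, 1e4, P)
    assert production_q(1e8, 2e4, P) / q1 == pytest.approx(2 ** P.beta)
    assert production_q(2e8, 1e4, P) / q1 == pytest.approx(2 ** P.alpha)
    assert production_q(1e8, 0.0, P) == 0.0
    with pytest.raises(ValueError):
        production_q(-1.0, 10.0, P)


def test_cost_and_marginal_cost_are_consistent():
    """MC equals the numerical derivative of C; C inverts the production
    function so that fishing the produced quantity costs w*DAS."""
    bio, w = 1.7e8, 1184.0
    for q in (1e7, 3e7, 6e7):
        h = q * 1e-6
        dc = (total_cost(q + h, bio, w, P) - total_cost(q - h, bio, w, P)) / (2 * h)
        assert marginal_cost(q, bio, w, P) == pytest.approx(dc, rel=1e-6)
    das = 25_000.0
    q = production_q(bio, das, P)
    assert total_cost(q, bio, w, P) == pytest.approx(w * das, rel=1e-9)


def test_marginal_cost_beta_one_degenerate_case():
    p1 = EconParams(beta=1.0 - 1e-12)
    mc1 = marginal_cost(1e7, 1.7e8, 1184.0, p1)
    mc2 = marginal_cost(5e7, 1.7e8, 1184.0, p1)
    assert mc1 == pytest.approx(mc2, rel=1e-6)


def test_marginal_crew_income_and_revenue():
    assert marginal_crew_income(6.0, 2.0, P) == pytest.approx(
        0.95 * 6.0 * 0.52 - 2.0)
    assert marginal_crew_income(6.0, 2.0, P) == pytest.approx(0.964)
    mc_breakeven = (1 - P.fee) * P.crew_share * 6.0
    assert marginal_crew_income(6.0, mc_breakeven, P) == pytest.approx(0.0)
    assert marginal_revenue(6.02) == 6.02
    prices = dict(EI["prices0"])
    shares = {"U10": 0.25, "11-20": 0.25, "21-30": 0.25, "31-40": 0.25}
    assert mean_price(prices, shares) == pytest.approx(
        np.mean(list(prices.values())))


# ---------------------------------------------------------------------------
# demand and prices


def test_demand_identity_and_update():
    d0 = EI["LAND0_lb"] - EI["exports_lb"] + EI["imports_lb"]
    assert d0 == EI["D0_lb"] == 78_903_000.0
    assert update_demand(d0, 0.0, 0.0, P) == d0
    r_d = P.e_p * 0.05 + P.e_i * 0.02
    assert r_d == pytest.approx(0.0182)
    assert update_demand(1e8, 0.05, 0.02, P) == pytest.approx(1e8 * (1 + r_d))
    with pytest.raises(RuntimeError):
        update_demand(1e8, 10.0, -10.0, P)


def test_price_surrogate_calibrated_to_year_2000():
    st = default_state()
    prices = update_prices(st, P)
    for cls, p0 in EI["prices0"].items():
        assert prices[cls] == pytest.approx(p0, rel=1e-12)
    assert prices["U10"] >= max(prices.values()) - 1e-12
    # zero thetas freeze prices
    p_flat = EconParams(theta_ip=0.0, theta_pcdi=0.0)
    st2 = default_state()
    st2.price_intercepts = calibrate_price_intercepts(
        st2.prices, st2.import_price, st2.pcdi, p_flat)
    st2.pcdi *= 2.0
    assert update_prices(st2, p_flat)["U10"] == pytest.approx(8.94)


def test_cost_per_day_fuel_passthrough():
    assert update_cost_per_day(1184.0, EI["FUEL0"], EI["FUEL0"], P) == 1184.0
    up = update_cost_per_day(1184.0, 2 * EI["FUEL0"], EI["FUEL0"], P)
    assert up == pytest.approx(1184.0 * (1 + P.fuel_share))


# ---------------------------------------------------------------------------
# decision step


def test_das_max_inverts_production():
    bio = EI["BIO0_lb"]
    for q in (1e7, 3e7):
        das = das_max(q, bio, P)
        assert production_q(bio, das, P) == pytest.approx(q, rel=1e-9)
    assert das_max(0.0, bio, P) == 0.0
    assert das_max(4e7, bio, P) > das_max(2e7, bio, P)


def test_das_to_f_linear_and_calibrated():
    f_das = calibrate_f_das(EI["LAND0_lb"], EI["BIO0_lb"], EI["DAS0"])
    assert das_to_F(0.0, f_das) == 0.0
    assert das_to_F(2 * EI["DAS0"], f_das) == pytest.approx(
        2 * das_to_F(EI["DAS0"], f_das))
    f0 = -math.log(1.0 - EI["LAND0_lb"] / EI["BIO0_lb"])
    assert das_to_F(EI["DAS0"], f_das) == pytest.approx(f0)


def test_optimizer_zero_quota_and_infeasibility():
    st = default_state()
    d = optimize_effort(0.0, 0.0, st, EI["BIO0_lb"], P)
    assert d.DAS == 0.0 and d.Q == 0.0


def test_optimizer_quota_binds_when_price_high_and_demand_slack():
    """With price far above cost and slack demand the fleet takes Q_ABC."""
    st = default_state(demand=1e10, w=10.0)
    st.prices = {k: 50.0 for k in st.prices}
    q_abc = 2e7
    cap = das_max(q_abc, EI["BIO0_lb"], P)
    d = optimize_effort(q_abc, cap, st, EI["BIO0_lb"], P)
    assert d.Q == pytest.approx(q_abc, rel=1e-3)
    assert d.binding["Q_abc"] or d.binding["DAS_max"]


def test_optimizer_matches_brute_force_on_random_instances(rng):
    """Optimum within one fine-grid cell of a 10^4-point exhaustive search."""
    for _ in range(12):
        bio = float(rng.uniform(5e7, 4e8))
        w = float(rng.uniform(300.0, 4000.0))
        price = float(rng.uniform(2.0, 12.0))
        demand = float(rng.uniform(2e7, 2e8))
        q_abc = float(rng.uniform(5e6, 8e7))
        st = default_state(demand=demand, w=w)
        st.prices = {k: price for k in st.prices}
        cap = das_max(q_abc, bio, P)
        d = optimize_effort(q_abc, cap, st, bio, P)

        grid = np.linspace(0.0, cap, 10_000)
        p_bar = mean_price(st.prices, st.shares)
        best = -np.inf
        best_das = 0.0
        for das in grid:
            q = production_q(bio, das, P) if das > 0 else 0.0
            if q - st.exports > demand:
                continue
            mc = marginal_cost(q, bio, w, P)
            if mc > marginal_crew_income(p_bar, mc, P):
                continue
            profit = p_bar * q - w * das
            if profit > best:
                best, best_das = profit, das
        cell = cap / 999.0
        assert d.DAS == pytest.approx(best_das, abs=cell + 1e-9)
        assert d.profit >= best - w * cell - 1e-6


def test_optimum_constraints_hold_and_binding_flags(rng):
    st = default_state()
    q_abc = 5e7
    cap = das_max(q_abc, EI["BIO0_lb"], P)
    d = optimize_effort(q_abc, cap, st, EI["BIO0_lb"], P)
    assert d.DAS <= cap * (1 + 1e-9)
    assert d.Q <= q_abc * (1 + 1e-9)
    assert d.Q - st.exports <= st.demand * (1 + 1e-9)
    assert d.MC <= d.MCI + 1e-6 * d.MR
    # relaxing a binding constraint weakly increases profit
    if d.binding["MC_MCI"]:
        relaxed = EconParams(crew_share=P.crew_share * 1.05)
        d2 = optimize_effort(q_abc, cap, st, EI["BIO0_lb"], relaxed)
        assert d2.profit >= d.profit - 1e-6


def test_production_parameter_recovery(rng):
    """Refitting (A, alpha, beta) from 50 noisy synthetic triples by OLS on
    logs recovers the truth within 2 standard errors."""
    import statsmodels.api as sm
    n = 50
    bio = rng.uniform(8e7, 3e8, n)
    das = rng.uniform(5e3, 6e4, n)
    q = np.array([production_q(b, d, P) for b, d in zip(bio, das)])
    q_noisy = q * np.exp(rng.normal(0.0, 0.05, n))
    X = sm.add_constant(np.column_stack([np.log(bio), np.log(das)]))
    fit = sm.OLS(np.log(q_noisy), X).fit()
    truth = [P.A, P.alpha, P.beta]
    for est, se, tr in zip(fit.params, fit.bse, truth):
        assert abs(est - tr) < 2.0 * se


def test_demand_stays_positive_over_50_years():
    d = 7.9e7
    for _ in range(50):
        d = update_demand(d, 0.01, 0.02, P)
        assert np.isfinite(d) and d > 0
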