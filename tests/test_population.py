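"""Size-structured population model: growth matrix against an
individual-based oracle, selectivity/weight arithmetic, Baranov catch
accounting, recruitment, and conservation properties."""

import math

import numpy as np
import pytest

from scallopiam.population import (DEFAULT_GRID, CatchAtSize, PopulationState,
                                   allocate_catch, beverton_holt,
                                   build_growth_matrix, exploitable_abundance,
                                   market_split, meat_weight,
                                   project_annual_catch, recruitment,
                                   selectivity, solve_annual_fishing_mortality,
                                   spawning_biomass, step_population,
                                   total_mortality)

GRID = DEFAULT_GRID


# ---------------------------------------------------------------------------
# growth matrix


def test_growth_matrix_columns_stochastic_no_shrinkage(gb, ma):
    for p in (gb, ma):
        for k_eff in (0.05, p.K, 0.8):
            G = build_growth_matrix(k_eff, p)
            np.testing.assert_allclose(G.P.sum(axis=0), 1.0, atol=1e-12)
            assert np.triu(G.P, 1).max(initial=0.0) == 0.0
            assert G.P.min() >= 0.0


def test_growth_matrix_identity_in_zero_growth_limit(gb):
    """As K -> 0 the matrix approaches the identity."""
    G = build_growth_matrix(1e-9, gb)
    assert np.allclose(G.P, np.eye(GRID.n), atol=1e-6)


def test_growth_matrix_plus_group_absorbing(gb):
    G = build_growth_matrix(gb.K, gb)
    assert G.P[-1, -1] == pytest.approx(1.0)


def test_growth_matrix_rejects_nonpositive_k(gb):
    with pytest.raises(ValueError):
        build_growth_matrix(0.0, gb)


@pytest.mark.parametrize("region_fixture,j", [("gb", 0), ("gb", 8), ("gb", 18),
                                              ("ma", 0), ("ma", 10), ("ma", 16)])
def test_growth_matrix_matches_individual_based_oracle(request, region_fixture, j):
    """Mean destination (binned) matches 1e5 individual VBGF draws within 2%
    of the mean increment."""
    p = request.getfixturevalue(region_fixture)
    G = build_growth_matrix(p.K, p)
    rng = np.random.default_rng(2024)
    n = 100_000
    u = rng.uniform(GRID.lower[j], GRID.lower[j] + GRID.width, n)
    hinf = rng.normal(p.H_inf, p.sigma_H_inf, n)
    k = np.maximum(rng.normal(p.K, p.sigma_K, n), 0.0)
    dest = u + np.maximum(hinf - u, 0.0) * (1.0 - np.exp(-k * 0.1))
    db = np.clip(np.searchsorted(GRID.edges, dest, side="right") - 1, j,
                 GRID.n - 1)
    mc_increment = GRID.mid[db].mean() - GRID.mid[j]
    matrix_increment = float(G.P[:, j] @ GRID.mid) - GRID.mid[j]
    assert matrix_increment == pytest.approx(
        mc_increment, abs=max(0.02 * abs(mc_increment), 0.02))


# ---------------------------------------------------------------------------
# per-size relationships


def test_selectivity_midpoint_and_monotonicity(gb):
    """Logistic midpoint at a_L/b_L (GB ~104.1 mm); ascending in H."""
    mid = gb.a_L / gb.b_L
    assert mid == pytest.approx(104.07, abs=0.05)
    assert selectivity(mid, gb) == pytest.approx(0.5, rel=1e-9)
    hs = np.linspace(40.0, 180.0, 100)
    s = selectivity(hs, gb)
    assert (np.diff(s) > 0).all()
    assert ((0 <= s) & (s <= 1)).all()


def test_domed_selectivity_suppresses_large_sizes(gb):
    s_asc = selectivity(170.0, gb)
    s_dome = selectivity(170.0, gb, domed=True)
    assert s_dome < s_asc
    assert selectivity(100.0, gb, domed=True) == pytest.approx(
        selectivity(100.0, gb), rel=0.05)


def test_meat_weight_arithmetic(gb):
    """GB 100 mm scallop weighs ~17.1 g; weight near MW_inf at H_inf."""
    assert meat_weight(100.0, gb) == pytest.approx(
        math.exp(-10.70 + 2.94 * math.log(100.0)), rel=1e-12)
    assert meat_weight(100.0, gb) == pytest.approx(17.1, abs=0.2)
    mw_at_hinf = meat_weight(gb.H_inf, gb)
    assert mw_at_hinf == pytest.approx(51.0, abs=1.5)
    assert 0.5 < mw_at_hinf / gb.MW_inf < 1.5  # same order as printed MW_inf
    hs = np.linspace(40, 180, 50)
    assert (np.diff(meat_weight(hs, gb)) > 0).all()


def test_market_split_categories(gb):
    """Meat-count boundaries: 50 g is U10, 20 g is 21-30; zero catch flagged."""
    w = np.zeros(GRID.n)
    # find the bin whose meat weight is closest to 50 g (count ~9.07/lb)
    mw = meat_weight(GRID.mid, gb)
    w[np.argmin(np.abs(mw - 50.0))] = 5.0
    fr, empty = market_split(w, gb)
    assert not empty and fr["U10"] == pytest.approx(1.0)
    w2 = np.zeros(GRID.n)
    w2[np.argmin(np.abs(mw - 20.0))] = 1.0
    fr2, _ = market_split(w2, gb)
    assert fr2["21-30"] == pytest.approx(1.0)
    fr0, empty0 = market_split(np.zeros(GRID.n), gb)
    assert empty0 and sum(fr0.values()) == 0.0
    assert sum(fr.values()) == pytest.approx(1.0)


def test_spawning_and_exploitable(gb):
    empty = PopulationState(region="GB", N=np.zeros(GRID.n))
    assert spawning_biomass(empty, gb) == 0.0
    assert exploitable_abundance(empty) == 0.0
    n = np.zeros(GRID.n)
    idx_100 = int(np.searchsorted(GRID.edges, 100.0, side="right") - 1)
    n[idx_100] = 1.0   # 1 million individuals in the 100-105 bin
    s = PopulationState(region="GB", N=n)
    assert spawning_biomass(s, gb) == pytest.approx(
        meat_weight(GRID.mid[idx_100], gb), rel=1e-12)
    assert exploitable_abundance(s) == 1.0
    n2 = np.zeros(GRID.n)
    n2[GRID.lower < 90.0] = 3.0
    assert exploitable_abundance(PopulationState(region="GB", N=n2)) == 0.0


# ---------------------------------------------------------------------------
# recruitment


def test_beverton_holt_limits(gb, ma):
    assert beverton_holt(0.0, gb) == 0.0
    a_gb = math.exp(gb.ln_aR) / 1e6
    assert beverton_holt(1e12, gb) == pytest.approx(a_gb, rel=1e-3)
    assert beverton_holt(50_000.0, ma) < math.exp(ma.ln_aR) / 1e6


def test_halving_larval_survival_worked_example(gb, ma):
    """Halving spawning stock cuts recruitment ~1.6% (GB) vs ~24% (MA):
    the GB curve is flat, the MA curve closer to linear."""
    s = 50_000.0
    red_gb = 1.0 - beverton_holt(0.5 * s, gb) / beverton_holt(s, gb)
    red_ma = 1.0 - beverton_holt(0.5 * s, ma) / beverton_holt(s, ma)
    assert red_gb == pytest.approx(0.016, abs=0.005)
    assert red_ma == pytest.approx(0.24, abs=0.05)
    assert red_ma > 10 * red_gb


def test_recruitment_deviate_is_unit_mean_ar1(gb, rng):
    """Lognormal deviates are bias-corrected (unit mean) and autocorrelated."""
    s = 50_000.0
    det = beverton_holt(s, gb)
    eps = 0.0
    draws, epss = [], []
    for _ in range(4000):
        r, eps = recruitment(s, gb, eps, rng)
        draws.append(r)
        epss.append(eps)
    draws = np.array(draws)
    epss = np.array(epss)
    assert draws.mean() == pytest.approx(det, rel=0.05)
    lag1 = np.corrcoef(epss[:-1], epss[1:])[0, 1]
    assert lag1 == pytest.approx(gb.rho, abs=0.05)


# ---------------------------------------------------------------------------
# mortality, catch, projection


def test_single_bin_baranov_closed_form(gb):
    """Survivors and catch in one bin match the closed-form Baranov values."""
    n = np.zeros(GRID.n)
    j = 15  # 115-120 mm, nearly fully selected
    n[j] = 10.0
    state = PopulationState(region="GB", N=n)
    G = build_growth_matrix(1e-9, gb)   # freeze growth to isolate mortality
    F = 0.3
    Z, F_land = total_mortality(F, gb)
    new, catch = step_population(state, G, F, gb, dt=0.1)
    assert new.N[j] == pytest.approx(10.0 * math.exp(-Z[j] * 0.1), rel=1e-6)
    expected_catch = F_land[j] / Z[j] * (1 - math.exp(-Z[j] * 0.1)) * 10.0
    assert catch.numbers[j] == pytest.approx(expected_catch, rel=1e-9)


def test_no_mortality_conserves_abundance(gb):
    from dataclasses import replace
    p0 = replace(gb, M=1e-12, I=0.0, D=0.0)
    state = PopulationState(region="GB", N=np.full(GRID.n, 1.0))
    G = build_growth_matrix(p0.K, p0)
    new, catch = step_population(state, G, 0.0, p0, dt=0.1)
    assert float(new.N.sum()) == pytest.approx(float(state.N.sum()), rel=1e-9)
    assert float(catch.numbers.sum()) == 0.0


def test_zero_fishing_zero_catch(gb, init_states):
    G = build_growth_matrix(gb.K, gb)
    _, catch = step_population(init_states["GB"], G, 0.0, gb)
    assert float(catch.weight_mT.sum()) == 0.0


def test_stationary_distribution_under_constant_forcing(gb):
    """Constant recruitment and F: the annual map reaches a fixed point that
    a longer brute-force projection confirms."""
    mats = [build_growth_matrix(gb.K, gb)] * 10
    state = PopulationState(region="GB", N=np.full(GRID.n, 10.0))
    for _ in range(60):
        state, _ = project_annual_catch(state, mats, 0.25, gb,
                                        recruits_in=500.0)
    n60 = state.N.copy()
    for _ in range(20):
        state, _ = project_annual_catch(state, mats, 0.25, gb,
                                        recruits_in=500.0)
    np.testing.assert_allclose(state.N, n60, rtol=1e-6, atol=1e-7)
    assert (state.N >= 0).all()


def test_solve_fleet_f_meets_quota(gb, init_states):
    """The solved F lands the requested quota within solver tolerance."""
    mats = [build_growth_matrix(gb.K, gb)] * 10
    state = init_states["GB"]
    _, at_03 = project_annual_catch(state, mats, 0.3, gb)
    quota = 0.6 * at_03
    F = solve_annual_fishing_mortality(state, mats, quota, gb)
    _, landed = project_annual_catch(state, mats, F, gb)
    assert landed == pytest.approx(quota, rel=1e-4)
    assert solve_annual_fishing_mortality(state, mats, 0.0, gb) == 0.0


def test_allocate_catch_shares(gb, ma, init_states):
    states = {"GB": init_states["GB"], "MA": init_states["MA"]}
    params = {"GB": gb, "MA": ma}
    q = allocate_catch(1000.0, states, params)
    assert sum(q.values()) == pytest.approx(1000.0)
    from scallopiam.population import exploitable_biomass
    r = exploitable_biomass(states["GB"], gb) / exploitable_biomass(states["MA"], ma)
    assert q["GB"] / q["MA"] == pytest.approx(r, rel=1e-9)
    empty = {"GB": PopulationState(region="GB", N=np.zeros(GRID.n)),
             "MA": init_states["MA"]}
    q2 = allocate_catch(1000.0, empty, params)
    assert q2["GB"] == 0.0 and q2["MA"] == pytest.approx(1000.0)
    both_empty = {r_: PopulationState(region=r_, N=np.zeros(GRID.n))
                  for r_ in ("GB", "MA")}
    with pytest.raises(RuntimeError):
        allocate_catch(1.0, both_empty, params)
    assert allocate_catch(0.0, both_empty, params) == {"GB": 0.0, "MA": 0.0}


def test_abundance_never_negative_under_heavy_fishing(gb, init_states):
    mats = [build_growth_matrix(gb.K, gb)] * 10
    state = init_states["GB"]
    for _ in range(5):
        state, _ = project_annual_catch(state, mats, 3.5, gb)
    assert (state.N >= 0).all()
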