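"""Coupled annual simulation of the scallop fishery system.

Each model year runs: (1) the management step — project the stock one year
at F_ABC to set the allowable biological catch Q_ABC and the days-at-sea
cap; (2) the fleet step — profit-maximizing effort under the management,
demand, and crew-income constraints; (3) ten sub-annual steps in which the
population grows (growth matrix rebuilt every step from the
environmentally adjusted Brody coefficient) and is fished at the rates
that realize the chosen catch, allocated across regions in proportion to
exploitable biomass; (4) annual spawning with the acidification-dependent
larval survival scaling feeding a 2-year recruitment pipeline; and (5)
market updates (prices, demand, costs).

The biogeochemical box model is integrated first over the whole horizon
and used as forcing, mirroring the one-way coupling of the source system.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import defaults as dflt
from .boxmodel import STEPS_PER_YEAR, run_boxmodel
from .coupling import (effective_K, larval_survival_scale,
                       oa_growth_delta, temperature_growth_delta)
from .economics import (EconState, calibrate_f_das,
                        calibrate_price_intercepts, das_max, das_to_F,
                        mean_price, optimize_effort, update_cost_per_day,
                        update_demand, update_prices)
from .population import (DEFAULT_GRID, allocate_catch, beverton_holt,
                         build_growth_matrix, exploitable_biomass,
                         project_annual_catch, recruitment, spawning_biomass,
                         step_population)
from .synthetic import ForcingSpec, SyntheticForcing, generate_synthetic_forcing

__all__ = ["ScenarioConfig", "ResultSet", "run_single", "run_hindcast",
           "run_ensemble"]

LB_PER_MT = 1000.0 / 0.45359237


@dataclass(frozen=True)
class ScenarioConfig:
    """Run configuration: scenario, horizon, couplings, seeds, forcing."""

    scenario: str = "rcp85"
    start_year: int = 2000
    end_year: int = 2050
    n_runs: int = 100
    seed: int = 0
    warming_2050: float | None = None      # None: scenario default
    enable_OA_recruitment: bool = True
    enable_OA_growth: bool = True
    enable_T_growth: bool = True
    hindcast_end: int = 2012
    forced_recruitment: bool = False       # override stochastic recruitment
    income_growth: float = 0.02            # yr-1 scenario constant
    domed_gb_selectivity: bool = False     # GB 2001-2003 domed gear variant
    param_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultSet:
    """Per-run annual tables, their ensemble aggregate, and run metadata."""

    runs: list
    aggregate: pd.DataFrame
    metadata: dict
    failures: list = field(default_factory=list)


def _scallop_params(config: ScenarioConfig) -> dict:
    out = {}
    for region in dflt.REGIONS:
        p = dflt.SCALLOP_DEFAULTS[region]
        over = {k.split(".", 2)[2]: v for k, v in config.param_overrides.items()
                if k.startswith(f"scallop.{region}.")}
        out[region] = replace(p, **over) if over else p
    return out


def _bgc_params(config: ScenarioConfig) -> dict:
    out = {}
    for region in dflt.REGIONS:
        p = dflt.BGC_DEFAULTS[region]
        over = {k.split(".", 2)[2]: v for k, v in config.param_overrides.items()
                if k.startswith(f"bgc.{region}.")}
        out[region] = replace(p, **over) if over else p
    return out


def _econ_params(config: ScenarioConfig):
    over = {k.split(".", 1)[1]: v for k, v in config.param_overrides.items()
            if k.startswith("econ.")}
    return replace(dflt.ECON_DEFAULTS, **over) if over else dflt.ECON_DEFAULTS


class _BGCForcing:
    """Box-model output reshaped for fast per-step lookup."""

    def __init__(self, config: ScenarioConfig, bgc_params: dict):
        scenario = dflt.co2_pathway(config.scenario, config.warming_2050)
        years = config.end_year - config.start_year + 1
        self.start_year = config.start_year
        self.deep_omega_ca = {}
        self.annual = {}
        for region in dflt.REGIONS:
            traj = run_boxmodel(scenario, bgc_params[region],
                                dflt.BGC_INITIAL[region], years)
            deep = traj.steps[traj.steps.box == "deep"]
            self.deep_omega_ca[region] = deep.omega_ca.to_numpy()
            self.annual[region] = traj.annual
        self.scenario = scenario

    def step_deep_omega_ca(self, region: str, year: int, istep: int) -> float:
        idx = (year - self.start_year) * STEPS_PER_YEAR + istep
        return float(self.deep_omega_ca[region][idx])

    def annual_mean(self, region: str, year: int, box: str, var: str) -> float:
        a = self.annual[region]
        sel = a[(a.year == year) & (a.box == box)]
        return float(sel[var].iloc[0])

    def lagged(self, region: str, year: int, box: str, var: str, lag: int) -> float:
        y = max(year - lag, self.start_year)
        return self.annual_mean(region, y, box, var)


def run_single(config: ScenarioConfig, run_seed: int | None = None,
               forcing: SyntheticForcing | None = None,
               bgc: _BGCForcing | None = None) -> pd.DataFrame:
    """One coupled trajectory; returns a tidy annual DataFrame.

    ``forcing`` supplies hindcast economic drivers and (when
    ``config.forced_recruitment``) the annual recruitment series through
    ``config.hindcast_end``; beyond it the run switches to stochastic
    recruitment and scenario-constant economic growth.
    """
    seed = config.seed if run_seed is None else run_seed
    sparams = _scallop_params(config)
    eparams = _econ_params(config)
    if bgc is None:
        bgc = _BGCForcing(config, _bgc_params(config))

    cpl = {}
    for region in dflt.REGIONS:
        cpl[region] = replace(
            dflt.COUPLING_DEFAULTS,
            omega_control=bgc.annual_mean(region, config.start_year, "deep", "omega_ca"),
            T_ref=bgc.annual_mean(region, config.start_year, "deep", "T"),
            enable_OA_recruitment=config.enable_OA_recruitment,
            enable_OA_growth=config.enable_OA_growth,
            enable_T_growth=config.enable_T_growth,
        )

    states = {r: dflt.initial_population_state(r) for r in dflt.REGIONS}
    rngs = {r: np.random.default_rng(np.random.SeedSequence([seed, i]))
            for i, r in enumerate(dflt.REGIONS)}
    for region in dflt.REGIONS:
        r0 = beverton_holt(spawning_biomass(states[region], sparams[region]),
                           sparams[region])
        states[region].pending_recruits = [r0, r0]

    ei = dflt.ECON_INITIAL
    econ = EconState(
        prices=dict(ei["prices0"]), import_price=ei["IP0"], pcdi=ei["PCDI0"],
        demand=ei["D0_lb"], fuel=ei["FUEL0"], w=ei["w0"],
        exports=ei["exports_lb"], shares=dict(ei["shares0"]),
    )
    econ.price_intercepts = calibrate_price_intercepts(
        econ.prices, econ.import_price, econ.pcdi, eparams)
    f_das = calibrate_f_das(ei["LAND0_lb"], ei["BIO0_lb"], ei["DAS0"])

    rows = []
    for year in range(config.start_year, config.end_year):
        in_hindcast = forcing is not None and year <= config.hindcast_end

        # economic drivers for this year
        pcdi_prev, ip_prev = econ.pcdi, econ.import_price
        if in_hindcast:
            f = forcing.econ[forcing.econ.year == year]
            if f.empty:
                raise RuntimeError(f"forcing gap: no economic forcing for {year}")
            econ.pcdi = float(f.PCDI.iloc[0])
            econ.import_price = float(f.import_price.iloc[0])
            econ.exports = float(f.exports.iloc[0])
            econ.fuel = float(f.fuel_price.iloc[0])
        else:
            econ.pcdi = pcdi_prev * (1.0 + config.income_growth)
            econ.fuel *= 1.0 + eparams.R_fuel / 100.0
        econ.w = update_cost_per_day(ei["w0"], econ.fuel, ei["FUEL0"], eparams)
        p_bar_prev = mean_price(econ.prices, econ.shares)
        econ.prices = update_prices(econ, eparams)
        p_bar = mean_price(econ.prices, econ.shares)

        domed = {r: (config.domed_gb_selectivity and r == "GB"
                     and 2001 <= year <= 2003) for r in dflt.REGIONS}

        # environmentally adjusted growth matrices, one per region and substep
        matrices = {}
        for region in dflt.REGIONS:
            p = sparams[region]
            t_lag2 = bgc.lagged(region, year, "deep", "T", 2)
            dK_T = temperature_growth_delta(t_lag2, cpl[region], p.K)
            mats = []
            for istep in range(STEPS_PER_YEAR):
                omega = bgc.step_deep_omega_ca(region, year, istep)
                dK_O = oa_growth_delta(omega, cpl[region], p.K)
                mats.append(build_growth_matrix(effective_K(p.K, dK_T, dK_O), p))
            matrices[region] = mats

        # recruits entering the 40-mm bin this year
        recruits_in = {}
        for region in dflt.REGIONS:
            if config.forced_recruitment and in_hindcast:
                recruits_in[region] = forcing.recruits(year, region)
            else:
                recruits_in[region] = states[region].pending_recruits[0]

        # management step: Q_ABC and DAS cap
        q_abc_mt = sum(
            project_annual_catch(states[r], matrices[r], sparams[r].F_abc,
                                 sparams[r], recruits_in=recruits_in[r],
                                 domed=domed[r])[1]
            for r in dflt.REGIONS)
        bio_mt = sum(spawning_biomass(states[r], sparams[r]) for r in dflt.REGIONS)
        bio_lb = bio_mt * LB_PER_MT
        q_abc_lb = q_abc_mt * LB_PER_MT
        cap = das_max(q_abc_lb, bio_lb, eparams)

        # fleet step
        decision = optimize_effort(q_abc_lb, cap, econ, bio_lb, eparams)
        decision.F_t = das_to_F(decision.DAS, f_das)

        # realize the catch: one fleet-wide F landing the chosen total Q_t
        # (the exploitable-biomass proportionality remains the quota
        # bookkeeping; a single fleet F matches Eq-7-style effort mapping)
        quotas_lb = allocate_catch(decision.Q, states, sparams)
        F_common = _solve_fleet_F(states, matrices, decision.Q / LB_PER_MT,
                                  sparams, recruits_in, domed)
        landings_w = np.zeros(DEFAULT_GRID.n)
        landed_by_region = {}
        spawn_pre = {r: spawning_biomass(states[r], sparams[r])
                     for r in dflt.REGIONS}
        f_realized = {r: F_common for r in dflt.REGIONS}
        for region in dflt.REGIONS:
            p = sparams[region]
            s = states[region]
            landed = 0.0
            for istep in range(STEPS_PER_YEAR):
                s, c = step_population(
                    s, matrices[region][istep], F_common, p,
                    recruits_in=recruits_in[region] if istep == 0 else 0.0,
                    domed=domed[region])
                landings_w += c.weight_mT
                landed += float(c.weight_mT.sum())
            states[region] = s
            landed_by_region[region] = landed

        # annual spawning into the 2-year pipeline
        for region in dflt.REGIONS:
            p = sparams[region]
            omega_lag2 = bgc.lagged(region, year, "surface", "omega_ar", 2)
            scale = larval_survival_scale(omega_lag2, cpl[region])
            s_eff = spawn_pre[region] * scale
            rec, eps = recruitment(s_eff, p, states[region].eps_prev, rngs[region])
            states[region].eps_prev = eps
            states[region].pending_recruits = [
                states[region].pending_recruits[1], rec]

        # market outcomes
        shares = _combined_market_shares(landings_w, sparams)
        empty = float(landings_w.sum()) <= 0.0
        landings_mt = float(landings_w.sum())
        landings_lb = landings_mt * LB_PER_MT
        revenue = sum(econ.prices[c] * shares[c] * landings_lb for c in shares)
        profit = revenue - econ.w * decision.DAS
        if not empty:
            econ.shares = shares
        r_p = (p_bar - p_bar_prev) / p_bar_prev
        r_i = (econ.pcdi - pcdi_prev) / pcdi_prev
        econ.demand = update_demand(econ.demand, r_p, r_i, eparams)

        row = {
            "year": year, "scenario": config.scenario,
            "landings_mT": landings_mt, "landings_lb": landings_lb,
            "Q_abc_lb": q_abc_lb, "DAS_max": cap, "DAS": decision.DAS,
            "Q_lb": decision.Q, "F_t": decision.F_t,
            "revenue_USD_2011": revenue, "cost_USD_2011": econ.w * decision.DAS,
            "profit_USD_2011": profit,
            "mean_price": p_bar, "demand_lb": econ.demand,
            "recruits_millions": sum(recruits_in.values()),
            "biomass_mT": sum(spawning_biomass(states[r], sparams[r])
                              for r in dflt.REGIONS),
            "abundance_millions": sum(float(states[r].N.sum())
                                      for r in dflt.REGIONS),
        }
        for c, v in shares.items():
            row[f"frac_{c}"] = v
        for region in dflt.REGIONS:
            row[f"biomass_mT_{region}"] = spawning_biomass(states[region],
                                                           sparams[region])
            row[f"F_{region}"] = f_realized[region]
            row[f"landings_mT_{region}"] = landed_by_region[region]
            row[f"spawning_mT_{region}"] = spawn_pre[region]
            for box in ("surface", "deep"):
                row[f"pH_{box}_{region}"] = bgc.annual_mean(region, year, box, "pH")
                row[f"omega_ca_{box}_{region}"] = bgc.annual_mean(
                    region, year, box, "omega_ca")
        rows.append(row)
    return pd.DataFrame(rows)


def _solve_fleet_F(states: dict, matrices: dict, quota_mt: float,
                   sparams: dict, recruits_in: dict, domed: dict) -> float:
    """Fleet-wide annual F whose combined projected landings meet ``quota_mt``.

    Bracketed solve on [0, 4 yr-1]; returns the upper bound when even that
    cannot land the quota (the quota then simply is not achieved).
    """
    from scipy.optimize import brentq

    if quota_mt <= 0:
        return 0.0

    def gap(F: float) -> float:
        tot = sum(project_annual_catch(states[r], matrices[r], F, sparams[r],
                                       recruits_in=recruits_in[r],
                                       domed=domed[r])[1]
                  for r in dflt.REGIONS)
        return tot - quota_mt

    F_MAX = 4.0
    if gap(F_MAX) < 0:
        return F_MAX
    return float(brentq(gap, 0.0, F_MAX, xtol=1e-6))


def _combined_market_shares(landings_w: np.ndarray, sparams: dict) -> dict:
    """Weight-based market shares of the combined catch-at-size vector.

    The two regions share the size grid; counts use the GB and MA
    weight-at-size averaged, an adequate approximation for whole-fishery
    category reporting.
    """
    from .population import GRAMS_PER_LB, MARKET_CLASSES, meat_weight
    total = float(landings_w.sum())
    if total <= 0:
        return {c: 0.0 for c in MARKET_CLASSES}
    mw = np.mean([meat_weight(DEFAULT_GRID.mid, p) for p in sparams.values()],
                 axis=0)
    counts = GRAMS_PER_LB / mw
    out = {c: 0.0 for c in MARKET_CLASSES}
    for w, cnt in zip(landings_w, counts):
        if cnt <= 10.0:
            out["U10"] += w
        elif cnt <= 20.0:
            out["11-20"] += w
        elif cnt <= 30.0:
            out["21-30"] += w
        else:
            out["31-40"] += w
    return {c: v / total for c, v in out.items()}


def run_hindcast(config: ScenarioConfig,
                 forcing: SyntheticForcing | None = None) -> ResultSet:
    """2000-2012-style hindcast with recruitment and economic forcing."""
    cfg = replace(config, forced_recruitment=True,
                  end_year=min(config.end_year, config.hindcast_end + 1))
    if forcing is None:
        forcing = generate_synthetic_forcing(
            ForcingSpec(start_year=cfg.start_year, end_year=cfg.hindcast_end),
            seed=cfg.seed)
    missing = set(range(cfg.start_year, cfg.end_year)) - set(
        forcing.econ.year.astype(int))
    if missing:
        raise RuntimeError(f"forcing gap: years {sorted(missing)} missing")
    df = run_single(cfg, forcing=forcing)
    meta = _metadata(cfg, [cfg.seed])
    return ResultSet(runs=[df], aggregate=_aggregate([df]), metadata=meta)


def run_ensemble(config: ScenarioConfig,
                 bgc: _BGCForcing | None = None) -> ResultSet:
    """Ensemble of ``config.n_runs`` stochastic runs with derived seeds.

    The biogeochemical forcing is deterministic per scenario and computed
    once. Per-run seeds derive from the master seed and run index only, so
    paired scenario comparisons share recruitment deviates. Failed runs are
    recorded with their exception, never silently dropped.
    """
    if bgc is None:
        bgc = _BGCForcing(config, _bgc_params(config))
    runs, failures = [], []
    for idx in range(config.n_runs):
        try:
            runs.append(run_single(config, run_seed=_run_seed(config.seed, idx),
                                   bgc=bgc))
        except Exception as exc:   # noqa: BLE001 - bookkeeping, not control flow
            failures.append({"run": idx, "error": repr(exc)})
    meta = _metadata(config, [_run_seed(config.seed, i)
                              for i in range(config.n_runs)])
    meta["n_failed"] = len(failures)
    return ResultSet(runs=runs, aggregate=_aggregate(runs), metadata=meta,
                     failures=failures)


def _run_seed(master: int, idx: int) -> int:
    h = hashlib.sha256(f"{master}:{idx}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _aggregate(runs: list) -> pd.DataFrame:
    if not runs:
        return pd.DataFrame()
    allruns = pd.concat(runs, keys=range(len(runs)), names=["run"])
    num = allruns.select_dtypes("number").drop(columns=["year"])
    num["year"] = allruns["year"]
    g = num.groupby("year")
    mean = g.mean().add_suffix("_mean")
    sd = g.std(ddof=0).add_suffix("_sd") if len(runs) > 1 else \
        g.mean().mul(0.0).add_suffix("_sd")
    return mean.join(sd).reset_index()


def _metadata(config: ScenarioConfig, seeds: list) -> dict:
    return {"config": asdict(config), "config_hash": config.config_hash(),
            "seeds": seeds, "package": "scallopiam"}
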