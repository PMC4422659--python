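"""Packaged default parameter sets and scenario fixtures.

Every numeric here is a printed value from the model's parameter and
initial-condition tables (regional biogeochemistry climatology fits,
scallop growth/mortality/recruitment, socioeconomic constants, and the
year-2000 initial states), plus the RCP8.5 atmospheric CO2 concentration
pathway shipped as a small packaged table. A provenance map records the
table row behind each parameter and is tested for completeness.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .boxmodel import BoxModelState, CO2Scenario, RegionBGCParams
from .coupling import CouplingParams
from .economics import EconParams
from .population import DEFAULT_GRID, PopulationState, ScallopParams, meat_weight

__all__ = [
    "REGIONS",
    "DefaultParameterSet",
    "load_defaults",
    "co2_pathway",
    "initial_population_state",
    "PROVENANCE",
    "YEAR0",
    "ATM_CO2_YEAR0",
]

REGIONS = ("GB", "MA")
YEAR0 = 2000
ATM_CO2_YEAR0 = 369.0        # ppm, observed year-2000 atmospheric CO2

BGC_DEFAULTS = {
    "MA": RegionBGCParams(
        region="MA", T1_mean=13.09, T2_mean=12.00, S1_mean=32.22, S2_mean=32.49,
        A_1T=14.48, A_1S=-1.46, A_2T=5.21,
        tau_1T=0.14, tau_1S=0.11, tau_2=0.19,
        phi_1S=-0.35, phi_1T=-0.63, phi_2T=-1.96,
        A_PP=0.27, phi_PP=-1.92, beta_PP=1.07,
        remin=1.00, pic_poc=0.04, f_ratio=0.25, K_s=1e-5,
        h1=22.0, h2=38.0,
        A_U=22.74, phi_U=4.41, beta_U=52.05,
    ),
    "GB": RegionBGCParams(
        region="GB", T1_mean=9.51, T2_mean=10.00, S1_mean=32.47, S2_mean=32.44,
        A_1T=9.00, A_1S=-0.75, A_2T=3.50,
        tau_1T=0.09, tau_1S=0.27, tau_2=0.15,
        phi_1S=-0.45, phi_1T=-0.97, phi_2T=-1.54,
        A_PP=0.58, phi_PP=-2.11, beta_PP=1.04,
        remin=0.80, pic_poc=0.04, f_ratio=0.25, K_s=1e-5,
        h1=25.0, h2=45.0,
        A_U=-33.84, phi_U=4.14, beta_U=54.23,
    ),
}

BGC_INITIAL = {
    "GB": BoxModelState(t=float(YEAR0), DIC_s=1890.1, DIC_d=2019.0,
                        TA_s=2160.6, TA_d=2125.7,
                        T1=23.29, T2=8.52, S1=31.67, S2=32.95),
    "MA": BoxModelState(t=float(YEAR0), DIC_s=1987.6, DIC_d=2042.8,
                        TA_s=2206.6, TA_d=2212.4,
                        T1=16.67, T2=9.06, S1=32.19, S2=32.67),
}

SCALLOP_DEFAULTS = {
    "GB": ScallopParams(
        region="GB", H_inf=144.9, sigma_H_inf=14.5, K=0.429, sigma_K=0.11,
        a_L=23.0, b_L=0.221, a_mw=-10.70, b_mw=2.94, MW_inf=54.7,
        M=0.12, I=0.1, D=0.2,
        ln_aR=20.17, sigma_ln_aR=0.202, ln_gammaR=6.664, sigma_ln_gammaR=2.871,
        rho=0.775, F_msy=0.38, F_abc=0.32,
    ),
    "MA": ScallopParams(
        region="MA", H_inf=132.1, sigma_H_inf=13.1, K=0.527, sigma_K=0.135,
        a_L=15.5, b_L=0.139, a_mw=-10.25, b_mw=2.85, MW_inf=46.6,
        M=0.15, I=0.2, D=0.2,
        ln_aR=21.35, sigma_ln_aR=0.341, ln_gammaR=10.073, sigma_ln_gammaR=0.464,
        rho=0.904, F_msy=0.38, F_abc=0.32,
    ),
}

ECON_DEFAULTS = EconParams()

# Year-2000 socioeconomic initial conditions (2011 USD)
ECON_INITIAL = {
    "FC0": 191_167.0,
    "ASSN0": 1_610.0,
    "COMM0": 3_446.0,
    "BIO0_lb": 172_458_000.0,
    "DAS0": 25_849.0,
    "FUEL0": 1.56,
    "w0": 1_184.0,
    "PCDI0": 25_946.0,
    "D0_lb": 78_903_000.0,
    "R0_millions": 3_728.0,
    "prices0": {"U10": 8.94, "11-20": 6.73, "21-30": 6.02, "31-40": 6.08},
    "LAND0_lb": 32_161_800.0,
    "N_MA_millions": 3_523.0,
    "N_GB_millions": 3_129.0,
    "exports_lb": 7_224_800.0,
    "IP0": 3.98,
    "imports_lb": 53_966_000.0,
    "shares0": {"U10": 0.07, "11-20": 0.20, "21-30": 0.42, "31-40": 0.21},
}

COUPLING_DEFAULTS = CouplingParams()


@dataclass(frozen=True)
class DefaultParameterSet:
    """Complete default configuration for one region."""

    region: str
    bgc: RegionBGCParams
    bgc_init: BoxModelState
    scallop: ScallopParams
    econ: EconParams
    coupling: CouplingParams


def load_defaults(region: str) -> DefaultParameterSet:
    """The packaged parameter set for ``region`` ('GB' or 'MA')."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    return DefaultParameterSet(
        region=region,
        bgc=BGC_DEFAULTS[region],
        bgc_init=BGC_INITIAL[region],
        scallop=SCALLOP_DEFAULTS[region],
        econ=ECON_DEFAULTS,
        coupling=COUPLING_DEFAULTS,
    )


# ---------------------------------------------------------------------------
# CO2 scenarios

def _rcp85_table() -> pd.DataFrame:
    with importlib.resources.files("scallopiam.data").joinpath("rcp85_co2.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def co2_pathway(name: str, warming_2050: float | None = None) -> CO2Scenario:
    """Named atmospheric CO2 scenario.

    ``rcp85``: the packaged RCP8.5 concentration pathway (annual linear
    interpolation) with a default 1.4 degC SST warming ramp to 2050.
    ``constant2008``: a flat control fixed at the pathway's 2008 value with
    no warming.
    """
    tab = _rcp85_table()
    years = tab["year"].to_numpy(dtype=float)
    co2 = tab["co2_ppm"].to_numpy(dtype=float)
    if name == "rcp85":
        return CO2Scenario(name="rcp85", years=years, co2_ppm=co2,
                           warming_2050=1.4 if warming_2050 is None else warming_2050)
    if name == "constant2008":
        c2008 = float(np.interp(2008.0, years, co2))
        return CO2Scenario(name="constant2008",
                           years=np.array([years[0], years[-1]]),
                           co2_ppm=np.array([c2008, c2008]),
                           warming_2050=0.0 if warming_2050 is None else warming_2050)
    raise ValueError(f"unknown scenario {name!r}; available: rcp85, constant2008")


# ---------------------------------------------------------------------------
# initial population state

def initial_population_state(region: str, biomass_share: dict | None = None
                             ) -> PopulationState:
    """Synthetic year-2000 size distribution matched to the printed totals.

    The survey size composition itself is not printed, so a smooth lognormal
    shell-height shape (mode near 85 mm) is tilted by exp(-lam*(H - 40)) with
    ``lam`` solved so that each region's mean meat weight reproduces its share
    of the printed initial biomass; abundance is scaled to the printed
    regional totals. By default biomass splits in proportion to abundance.
    """
    from scipy.optimize import brentq

    p = SCALLOP_DEFAULTS[region]
    n_tot = {"GB": ECON_INITIAL["N_GB_millions"], "MA": ECON_INITIAL["N_MA_millions"]}
    bio_tot_mT = ECON_INITIAL["BIO0_lb"] * 0.45359237 / 1000.0
    if biomass_share is None:
        tot = sum(n_tot.values())
        biomass_share = {r: n_tot[r] / tot for r in n_tot}
    target_mw = bio_tot_mT * biomass_share[region] / n_tot[region]  # g per individual

    mid = DEFAULT_GRID.mid
    mw = meat_weight(mid, p)
    base = np.exp(-0.5 * ((np.log(mid) - math.log(85.0)) / 0.28) ** 2)
    base[mid > p.H_inf + 2 * p.sigma_H_inf] = 0.0

    def mean_mw(lam: float) -> float:
        w = base * np.exp(-lam * (mid - 40.0))
        return float(np.sum(w * mw) / np.sum(w))

    lam = brentq(lambda l: mean_mw(l) - target_mw, -0.2, 0.2)
    shape = base * np.exp(-lam * (mid - 40.0))
    N = shape / shape.sum() * n_tot[region]
    return PopulationState(region=region, N=N)


# ---------------------------------------------------------------------------
# provenance: parameter -> table row

def _rows(prefix: str, obj, table: str) -> dict:
    return {f"{prefix}.{f.name}": table for f in fields(obj)}


PROVENANCE: dict[str, str] = {}
for _r in REGIONS:
    PROVENANCE.update(_rows(f"bgc.{_r}", BGC_DEFAULTS[_r], "BGC parameter table (Table 1)"))
    PROVENANCE.update(_rows(f"bgc_init.{_r}", BGC_INITIAL[_r],
                            "BGC initial conditions (Table 4)"))
    PROVENANCE.update(_rows(f"scallop.{_r}", SCALLOP_DEFAULTS[_r],
                            "scallop parameter table (Table 2)"))
PROVENANCE.update(_rows("econ", ECON_DEFAULTS, "socioeconomic parameter table (Table 3)"))
PROVENANCE.update({f"econ_init.{k}": "year-2000 initial conditions (Table 5)"
                   for k in ECON_INITIAL})
PROVENANCE.update(_rows("coupling", COUPLING_DEFAULTS,
                        "biogeochemistry-scallop coupling (Eqs 8-9 / meta-analysis)"))
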