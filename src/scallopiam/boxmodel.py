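"""Two-box shelf carbonate-chemistry model.

One vertically stratified water column per region (Georges Bank, Mid-Atlantic
Bight): a surface box of thickness ``h1`` and a deep (benthic) box of
thickness ``h2``. Temperature, salinity, wind speed squared, and primary
production are prescribed seasonal sinusoids fitted to regional
climatologies; DIC and TA are prognostic, forced by air-sea CO2 exchange,
biological production/remineralization and CaCO3 cycling, vertical diffusive
mixing, and wintertime convective overturning. The carbonate system is
resolved in both boxes at every step and annual means of pH and saturation
state force the scallop population model.

Numerical scheme: forward Euler at dt = 1/10 yr, matching the population
model's sub-annual step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .carbonate import CarbonateState, compute_constants, solve_from_dic_ta

__all__ = [
    "RegionBGCParams",
    "BoxModelState",
    "CO2Scenario",
    "BGCTrajectory",
    "seasonal_climatology",
    "apply_warming",
    "gas_exchange_tendency",
    "biological_tendencies",
    "mixing_tendencies",
    "seawater_density",
    "run_boxmodel",
]

DT = 0.1                    # yr, model sub-annual step
STEPS_PER_YEAR = 10
RHO_SW = 1025.0             # kg m-3, areal <-> per-mass conversions
GC_TO_MOL = 1.0 / 12.011    # mol gC-1
DAYS_PER_YEAR = 365.0
SECONDS_PER_YEAR = 86400.0 * DAYS_PER_YEAR
HOURS_PER_YEAR = 24.0 * DAYS_PER_YEAR
GAS_TRANSFER_COEF = 0.251   # (cm hr-1)(m s-1)-2, quadratic-wind transfer


@dataclass(frozen=True)
class RegionBGCParams:
    """Biogeochemical parameters for one region (climatology fits + rates).

    Sinusoid convention: X(t) = mean + amplitude * sin(2*pi*(t + phase)) with
    t in decimal years and phases in years. The relaxation rates tau_* are
    carried for completeness but unused by the default dynamics (their
    functional role is not recoverable from the published description).
    """

    region: str
    T1_mean: float          # degC, surface temperature climatological mean
    T2_mean: float          # degC, deep
    S1_mean: float          # psu, surface salinity
    S2_mean: float          # psu, deep (held constant seasonally)
    A_1T: float             # seasonal amplitudes
    A_1S: float
    A_2T: float
    tau_1T: float           # yr-1, retained but unused
    tau_1S: float
    tau_2: float
    phi_1S: float           # yr, seasonal phases
    phi_1T: float
    phi_2T: float
    A_PP: float             # gC m-2 d-1, primary-production sinusoid
    phi_PP: float
    beta_PP: float
    remin: float            # fraction of export remineralized in deep box
    pic_poc: float          # CaCO3:organic production ratio
    f_ratio: float          # export fraction of primary production
    K_s: float              # m2 s-1, vertical diffusivity
    h1: float               # m, box thicknesses
    h2: float
    A_U: float              # m2 s-2, wind-speed-squared sinusoid
    phi_U: float
    beta_U: float

    def __post_init__(self) -> None:
        if self.h1 <= 0 or self.h2 <= 0:
            raise ValueError("box thicknesses must be positive")
        if not (0.0 <= self.remin <= 1.0 and 0.0 <= self.f_ratio <= 1.0):
            raise ValueError("remin and f_ratio must lie in [0, 1]")
        if self.pic_poc < 0:
            raise ValueError("pic_poc must be non-negative")


@dataclass
class BoxModelState:
    """Prognostic tracers and prescribed T/S for one region at time ``t``."""

    t: float                # decimal year
    DIC_s: float            # µmol kg-1
    DIC_d: float
    TA_s: float
    TA_d: float
    T1: float               # degC
    T2: float
    S1: float               # psu
    S2: float

    def column_inventory(self, h1: float, h2: float, tracer: str = "DIC") -> float:
        """Depth-integrated tracer content h1*C_s + h2*C_d (µmol kg-1 m)."""
        if tracer == "DIC":
            return h1 * self.DIC_s + h2 * self.DIC_d
        if tracer == "TA":
            return h1 * self.TA_s + h2 * self.TA_d
        raise ValueError(f"unknown tracer {tracer!r}")


@dataclass(frozen=True)
class CO2Scenario:
    """Atmospheric CO2 pathway plus optional linear SST warming ramp.

    ``warming_2050`` is the total warming (degC) reached at 2050, ramped
    linearly from zero at 2000 and held constant beyond 2050.
    """

    name: str
    years: np.ndarray = field(repr=False)
    co2_ppm: np.ndarray = field(repr=False)
    warming_2050: float = 0.0

    def pco2_atm(self, t: float) -> float:
        """Atmospheric pCO2 (µatm ~ ppm) at decimal year ``t``."""
        return float(np.interp(t, self.years, self.co2_ppm))


@dataclass
class BGCTrajectory:
    """Step-level and annual-mean output of one box-model run."""

    region: str
    steps: pd.DataFrame     # one row per sub-annual step and box
    annual: pd.DataFrame    # one row per calendar year and box


def seasonal_climatology(t: float, p: RegionBGCParams):
    """Prescribed (T1, T2, S1, S2, U2, PP) at decimal year ``t``.

    U2 (m2 s-2) and PP (gC m-2 d-1) are clamped at zero; deep salinity is
    held at its climatological mean.
    """
    def sinus(mean, amp, phase):
        return mean + amp * math.sin(2.0 * math.pi * (t + phase))

    T1 = sinus(p.T1_mean, p.A_1T, p.phi_1T)
    T2 = sinus(p.T2_mean, p.A_2T, p.phi_2T)
    S1 = sinus(p.S1_mean, p.A_1S, p.phi_1S)
    S2 = p.S2_mean
    U2 = max(0.0, sinus(p.beta_U, p.A_U, p.phi_U))
    PP = max(0.0, sinus(p.beta_PP, p.A_PP, p.phi_PP))
    return T1, T2, S1, S2, U2, PP


def apply_warming(T: float, t: float, scenario: CO2Scenario,
                  start: float = 2000.0, end: float = 2050.0) -> float:
    """Add the scenario's linear warming ramp to a climatological temperature."""
    frac = min(max((t - start) / (end - start), 0.0), 1.0)
    return T + scenario.warming_2050 * frac


def schmidt_number(T: float) -> float:
    """Schmidt number of CO2 in seawater (Wanninkhof 2014 polynomial)."""
    return (2116.8 - 136.25 * T + 4.7353 * T ** 2
            - 0.092307 * T ** 3 + 0.0007555 * T ** 4)


def gas_exchange_tendency(surface: CarbonateState, pCO2_atm: float,
                          U2: float, h1: float) -> float:
    """Surface-box DIC tendency (µmol kg-1 yr-1) from air-sea CO2 exchange.

    Quadratic-wind transfer velocity k_w = 0.251 * U2 * (Sc/660)^-1/2 in
    cm hr-1; positive flux into the ocean. The seawater density cancels
    between the areal flux and the per-mass tendency.
    """
    if h1 <= 0:
        raise ValueError("surface box thickness must be positive")
    sc = schmidt_number(surface.T)
    kw_cm_hr = GAS_TRANSFER_COEF * U2 * (sc / 660.0) ** -0.5
    kw_m_yr = kw_cm_hr * 0.01 * HOURS_PER_YEAR
    k0 = compute_constants(surface.T, surface.S).K0   # mol kg-1 atm-1
    return kw_m_yr / h1 * k0 * (pCO2_atm - surface.pCO2)


def biological_tendencies(PP: float, p: RegionBGCParams):
    """Per-box (dDIC, dTA) tendencies (µmol kg-1 yr-1) from biology.

    Surface: export production ``f_ratio*PP`` removes DIC; CaCO3 production
    ``pic_poc*PP`` removes DIC and twice as much TA (mol basis). Deep:
    ``remin`` of the export is remineralized back to DIC and all exported
    CaCO3 redissolves. The un-remineralized organic fraction is a net column
    sink balanced at steady state by air-sea influx.
    """
    if PP < 0:
        raise ValueError(f"primary production must be non-negative, got {PP}")
    pp_mol = PP * GC_TO_MOL * DAYS_PER_YEAR        # mol C m-2 yr-1
    export = p.f_ratio * pp_mol
    caco3 = p.pic_poc * pp_mol

    to_umol_s = 1e6 / (p.h1 * RHO_SW)
    to_umol_d = 1e6 / (p.h2 * RHO_SW)
    dDIC_s = -(export + caco3) * to_umol_s
    dTA_s = -2.0 * caco3 * to_umol_s
    dDIC_d = (p.remin * export + caco3) * to_umol_d
    dTA_d = 2.0 * caco3 * to_umol_d
    return (dDIC_s, dTA_s), (dDIC_d, dTA_d)


def seawater_density(S: float, T: float) -> float:
    """Surface-pressure seawater density (kg m-3), UNESCO 1983 EOS-80."""
    rho_w = (999.842594 + 6.793952e-2 * T - 9.095290e-3 * T ** 2
             + 1.001685e-4 * T ** 3 - 1.120083e-6 * T ** 4
             + 6.536332e-9 * T ** 5)
    A = (8.24493e-1 - 4.0899e-3 * T + 7.6438e-5 * T ** 2
         - 8.2467e-7 * T ** 3 + 5.3875e-9 * T ** 4)
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T ** 2
    C = 4.8314e-4
    return rho_w + A * S + B * S ** 1.5 + C * S ** 2


def mixing_tendencies(state: BoxModelState, p: RegionBGCParams):
    """Diffusive exchange tendencies for DIC and TA, per box (µmol kg-1 yr-1).

    Exchange velocity v = K_s / ((h1+h2)/2). Returns
    ((dDIC_s, dTA_s), (dDIC_d, dTA_d)); the pair conserves the column
    inventory exactly: h1*dC_s + h2*dC_d = 0.
    """
    v = p.K_s * SECONDS_PER_YEAR / (0.5 * (p.h1 + p.h2))   # m yr-1
    dDIC = v * (state.DIC_d - state.DIC_s)
    dTA = v * (state.TA_d - state.TA_s)
    return (dDIC / p.h1, dTA / p.h1), (-dDIC / p.h2, -dTA / p.h2)


def is_convective(state: BoxModelState) -> bool:
    """True when the prescribed T/S make the column statically unstable."""
    return seawater_density(state.S1, state.T1) >= seawater_density(state.S2, state.T2)


def _homogenize(state: BoxModelState, p: RegionBGCParams) -> None:
    wtot = p.h1 + p.h2
    dic = (p.h1 * state.DIC_s + p.h2 * state.DIC_d) / wtot
    ta = (p.h1 * state.TA_s + p.h2 * state.TA_d) / wtot
    state.DIC_s = state.DIC_d = dic
    state.TA_s = state.TA_d = ta


def run_boxmodel(scenario: CO2Scenario, p: RegionBGCParams,
                 init: BoxModelState, years: int,
                 gas_exchange: bool = True, biology: bool = True,
                 mixing: bool = True, convection: bool = True) -> BGCTrajectory:
    """Integrate one region's column for ``years`` years from ``init``.

    T/S are prescribed (climatology + warming ramp); DIC/TA are prognostic.
    The carbonate system is resolved in both boxes every step and annual
    means are computed over exactly 10 steps. The process switches exist for
    conservation and ablation tests.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    state = replace(init)
    t0 = init.t
    rows = []
    for istep in range(years * STEPS_PER_YEAR):
        t = t0 + istep * DT
        T1c, T2c, S1, S2, U2, PP = seasonal_climatology(t, p)
        state.T1 = apply_warming(T1c, t, scenario)
        state.T2 = apply_warming(T2c, t, scenario)
        state.S1, state.S2 = S1, S2
        state.t = t

        try:
            surf = solve_from_dic_ta(state.DIC_s, state.TA_s, state.T1, state.S1)
            deep = solve_from_dic_ta(state.DIC_d, state.TA_d, state.T2, state.S2)
        except (RuntimeError, ValueError) as exc:
            raise RuntimeError(
                f"carbonate solver failed at step {istep} (t={t:.2f}, "
                f"region {p.region}): {exc}"
            ) from exc

        for box, cs in (("surface", surf), ("deep", deep)):
            rows.append({
                "time": t, "year": int(math.floor(t0)) + istep // STEPS_PER_YEAR,
                "region": p.region, "box": box,
                "DIC": cs.DIC, "TA": cs.TA, "T": cs.T, "S": cs.S,
                "pH": cs.pH, "pCO2": cs.pCO2,
                "omega_ar": cs.omega_ar, "omega_ca": cs.omega_ca,
            })

        dDIC_s = dTA_s = dDIC_d = dTA_d = 0.0
        if gas_exchange:
            dDIC_s += gas_exchange_tendency(surf, scenario.pco2_atm(t), U2, p.h1)
        if biology:
            (bs_dic, bs_ta), (bd_dic, bd_ta) = biological_tendencies(PP, p)
            dDIC_s += bs_dic
            dTA_s += bs_ta
            dDIC_d += bd_dic
            dTA_d += bd_ta
        if mixing:
            (ms_dic, ms_ta), (md_dic, md_ta) = mixing_tendencies(state, p)
            dDIC_s += ms_dic
            dTA_s += ms_ta
            dDIC_d += md_dic
            dTA_d += md_ta

        state.DIC_s += dDIC_s * DT
        state.TA_s += dTA_s * DT
        state.DIC_d += dDIC_d * DT
        state.TA_d += dTA_d * DT
        if convection and is_convective(state):
            _homogenize(state, p)

    steps = pd.DataFrame(rows)
    annual = (steps
              .groupby(["year", "region", "box"], as_index=False)
              [["DIC", "TA", "T", "S", "pH", "pCO2", "omega_ar", "omega_ca"]]
              .mean())
    return BGCTrajectory(region=p.region, steps=steps, annual=annual)
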