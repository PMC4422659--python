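"""Seawater CO2-system solver.

Solves the marine carbonate system from (DIC, TA) or (TA, pCO2) at a given
temperature and salinity, on the total pH scale at surface pressure, and
reports pH, pCO2, carbonate ion, and the calcite/aragonite saturation states
that drive the shellfish responses elsewhere in the package.

Constants dialect (documented here, configurable via :class:`ConstantsDialect`):

* K1, K2 : Lueker, Dickson & Keeling (2000) -- Mehrbach refit, total scale
* K0     : Weiss (1974) CO2 solubility
* KB     : Dickson (1990b), total scale
* KW     : Millero (1995), seawater scale, converted to total
* KS     : Dickson (1990a), free scale
* KF     : Dickson & Riley (1979), free scale
* Ksp    : Mucci (1983) calcite and aragonite stoichiometric products
* BT     : Uppstrom (1974) total boron; sulfate/fluoride/calcium from the
           standard salinity proportionalities (Riley & Tongudai for Ca).

Nutrient (phosphate/silicate) alkalinity is omitted: the box model carries
DIC and TA only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


from scipy.optimize import brentq

__all__ = [
    "EquilibriumConstants",
    "CarbonateState",
    "compute_constants",
    "solve_from_dic_ta",
    "solve_from_ta_pco2",
    "saturation_state",
]

# pH search bracket and alkalinity-residual tolerance (µmol kg-1)
PH_MIN, PH_MAX = 3.0, 12.0
PH_TOL = 1e-10
TA_RESIDUAL_TOL = 1e-3


@dataclass(frozen=True)
class ConstantsDialect:
    """Switchboard for the equilibrium-constant formulations.

    Only one dialect is implemented; the dataclass records the choice in run
    metadata and guards against silent divergence if alternatives are added.
    """

    k1k2: str = "lueker2000"
    kso4: str = "dickson1990"
    boron: str = "uppstrom1974"
    ph_scale: str = "total"


DEFAULT_DIALECT = ConstantsDialect()


@dataclass(frozen=True)
class EquilibriumConstants:
    """Thermodynamic constants of the CO2 system (total scale, mol kg-1 units).

    K0 in mol kg-1 atm-1, Ksp in (mol kg-1)^2; BT, TS, TF, Ca are total
    concentrations in mol kg-1.
    """

    K0: float
    K1: float
    K2: float
    KB: float
    KW: float
    KS: float
    KF: float
    Ksp_ca: float
    Ksp_ar: float
    BT: float
    TS: float
    TF: float
    Ca: float
    free_to_total: float


@dataclass(frozen=True)
class CarbonateState:
    """Full carbonate-system solution for one water parcel.

    Concentrations in µmol kg-1, pCO2 in µatm, pH on the total scale.
    """

    DIC: float
    TA: float
    T: float
    S: float
    pH: float
    pCO2: float
    CO3: float
    omega_ar: float
    omega_ca: float


def compute_constants(T: float, S: float) -> EquilibriumConstants:
    """Equilibrium constants at temperature ``T`` (degC) and salinity ``S`` (psu).

    Valid for -2 <= T <= 40 (down to the seawater freezing point, which the
    winter shelf climatology reaches) and 20 <= S <= 40; surface pressure.
    """
    if not -2.0 <= T <= 40.0:
        raise ValueError(f"temperature {T} degC outside supported range [-2, 40]")
    if not 20.0 <= S <= 40.0:
        raise ValueError(f"salinity {S} psu outside supported range [20, 40]")

    TK = T + 273.15
    lnTK = math.log(TK)
    sqS = math.sqrt(S)

    # --- total concentrations from salinity
    BT = 0.0004157 * S / 35.0                      # Uppstrom 1974
    TS = (0.14 / 96.062) * (S / 1.80655)           # Morris & Riley 1966
    TF = (0.000067 / 18.998) * (S / 1.80655)       # Riley 1965
    Ca = (0.02128 / 40.087) * (S / 1.80655)        # Riley & Tongudai 1967

    # --- bisulfate (free scale) Dickson 1990a
    ion_str = 19.924 * S / (1000.0 - 1.005 * S)
    sqI = math.sqrt(ion_str)
    lnKS = (
        -4276.1 / TK + 141.328 - 23.093 * lnTK
        + (-13856.0 / TK + 324.57 - 47.986 * lnTK) * sqI
        + (35474.0 / TK - 771.54 + 114.723 * lnTK) * ion_str
        - 2698.0 / TK * ion_str ** 1.5
        + 1776.0 / TK * ion_str ** 2
        + math.log(1.0 - 0.001005 * S)
    )
    KS = math.exp(lnKS)

    # --- hydrogen fluoride (free scale) Dickson & Riley 1979
    lnKF = 1590.2 / TK - 12.641 + 1.525 * sqI + math.log(1.0 - 0.001005 * S)
    KF = math.exp(lnKF)

    free_to_total = 1.0 + TS / KS
    sws_to_total = free_to_total / (1.0 + TS / KS + TF / KF)

    # --- CO2 solubility, Weiss 1974 (mol kg-1 atm-1)
    TK100 = TK / 100.0
    lnK0 = (
        -60.2409 + 93.4517 / TK100 + 23.3585 * math.log(TK100)
        + S * (0.023517 - 0.023656 * TK100 + 0.0047036 * TK100 ** 2)
    )
    K0 = math.exp(lnK0)

    # --- carbonic acid, Lueker et al. 2000 (total scale)
    pK1 = 3633.86 / TK - 61.2172 + 9.67770 * lnTK - 0.011555 * S + 0.0001152 * S ** 2
    pK2 = 471.78 / TK + 25.9290 - 3.16967 * lnTK - 0.01781 * S + 0.0001122 * S ** 2
    K1 = 10.0 ** (-pK1)
    K2 = 10.0 ** (-pK2)

    # --- boric acid, Dickson 1990b (total scale)
    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S ** 1.5 - 0.0996 * S ** 2) / TK
        + 148.0248 + 137.1942 * sqS + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnTK
        + 0.053105 * sqS * TK
    )
    KB = math.exp(lnKB)

    # --- water, Millero 1995 (seawater scale -> total)
    lnKW = (
        148.9802 - 13847.26 / TK - 23.6521 * lnTK
        + (118.67 / TK - 5.977 + 1.0495 * lnTK) * sqS
        - 0.01615 * S
    )
    KW = math.exp(lnKW) * sws_to_total

    # --- stoichiometric solubility products, Mucci 1983
    log10Kca = (
        -171.9065 - 0.077993 * TK + 2839.319 / TK + 71.595 * math.log10(TK)
        + (-0.77712 + 0.0028426 * TK + 178.34 / TK) * sqS
        - 0.07711 * S + 0.0041249 * S ** 1.5
    )
    log10Kar = (
        -171.945 - 0.077993 * TK + 2903.293 / TK + 71.595 * math.log10(TK)
        + (-0.068393 + 0.0017276 * TK + 88.135 / TK) * sqS
        - 0.10018 * S + 0.0059415 * S ** 1.5
    )
    Ksp_ca = 10.0 ** log10Kca
    Ksp_ar = 10.0 ** log10Kar

    return EquilibriumConstants(
        K0=K0, K1=K1, K2=K2, KB=KB, KW=KW, KS=KS, KF=KF,
        Ksp_ca=Ksp_ca, Ksp_ar=Ksp_ar, BT=BT, TS=TS, TF=TF, Ca=Ca,
        free_to_total=free_to_total,
    )


def _alkalinity(h: float, dic: float, k: EquilibriumConstants) -> float:
    """Total alkalinity (mol kg-1) at total-scale [H+] ``h`` and DIC (mol kg-1)."""
    denom = h * h + k.K1 * h + k.K1 * k.K2
    hco3 = dic * k.K1 * h / denom
    co3 = dic * k.K1 * k.K2 / denom
    boh4 = k.BT * k.KB / (k.KB + h)
    oh = k.KW / h
    h_free = h / k.free_to_total
    hso4 = k.TS / (1.0 + k.KS / h_free)
    hf = k.TF / (1.0 + k.KF / h_free)
    return hco3 + 2.0 * co3 + boh4 + oh - h_free - hso4 - hf


def _state_from_h(h: float, dic: float, ta: float, T: float, S: float,
                  k: EquilibriumConstants) -> CarbonateState:
    denom = h * h + k.K1 * h + k.K1 * k.K2
    co2aq = dic * h * h / denom
    co3 = dic * k.K1 * k.K2 / denom
    pco2 = co2aq / k.K0 * 1e6
    omega_ca = k.Ca * co3 / k.Ksp_ca
    omega_ar = k.Ca * co3 / k.Ksp_ar
    return CarbonateState(
        DIC=dic * 1e6, TA=ta * 1e6, T=T, S=S,
        pH=-math.log10(h), pCO2=pco2, CO3=co3 * 1e6,
        omega_ar=omega_ar, omega_ca=omega_ca,
    )


def solve_from_dic_ta(DIC: float, TA: float, T: float, S: float,
                      constants: EquilibriumConstants | None = None) -> CarbonateState:
    """Solve the CO2 system from DIC and TA (both µmol kg-1).

    Finds the unique chemically valid [H+] root of the alkalinity balance by
    Brent's method over pH in (3, 12); the returned state satisfies
    |TA(pH) - TA| < 1e-3 µmol kg-1.
    """
    if DIC <= 0 or TA <= 0:
        raise ValueError(f"DIC and TA must be positive, got DIC={DIC}, TA={TA}")
    k = constants if constants is not None else compute_constants(T, S)
    dic = DIC * 1e-6
    ta = TA * 1e-6

    def resid(ph: float) -> float:
        return _alkalinity(10.0 ** (-ph), dic, k) - ta

    lo, hi = resid(PH_MIN), resid(PH_MAX)
    if lo * hi > 0:
        raise RuntimeError(
            f"no alkalinity root in pH ({PH_MIN}, {PH_MAX}); "
            f"residuals {lo * 1e6:.3g}/{hi * 1e6:.3g} µmol kg-1"
        )
    ph = brentq(resid, PH_MIN, PH_MAX, xtol=PH_TOL)
    if abs(resid(ph)) * 1e6 > TA_RESIDUAL_TOL:
        raise RuntimeError(
            f"alkalinity residual {resid(ph) * 1e6:.3g} µmol kg-1 exceeds tolerance"
        )
    return _state_from_h(10.0 ** (-ph), dic, ta, T, S, k)


def solve_from_ta_pco2(TA: float, pCO2: float, T: float, S: float,
                       constants: EquilibriumConstants | None = None) -> CarbonateState:
    """Solve the CO2 system from TA (µmol kg-1) and pCO2 (µatm).

    Inverse companion of :func:`solve_from_dic_ta`; the pair round-trips to
    better than 0.01 µmol kg-1 in DIC.
    """
    if TA <= 0 or pCO2 <= 0:
        raise ValueError(f"TA and pCO2 must be positive, got TA={TA}, pCO2={pCO2}")
    k = constants if constants is not None else compute_constants(T, S)
    ta = TA * 1e-6
    co2aq = k.K0 * pCO2 * 1e-6

    def resid(ph: float) -> float:
        h = 10.0 ** (-ph)
        hco3 = k.K1 * co2aq / h
        co3 = k.K1 * k.K2 * co2aq / (h * h)
        boh4 = k.BT * k.KB / (k.KB + h)
        oh = k.KW / h
        h_free = h / k.free_to_total
        hso4 = k.TS / (1.0 + k.KS / h_free)
        hf = k.TF / (1.0 + k.KF / h_free)
        return hco3 + 2.0 * co3 + boh4 + oh - h_free - hso4 - hf - ta

    lo, hi = resid(PH_MIN), resid(PH_MAX)
    if lo * hi > 0:
        raise RuntimeError(f"no alkalinity root in pH ({PH_MIN}, {PH_MAX})")
    ph = brentq(resid, PH_MIN, PH_MAX, xtol=PH_TOL)
    h = 10.0 ** (-ph)
    dic = co2aq * (1.0 + k.K1 / h + k.K1 * k.K2 / (h * h))
    return _state_from_h(h, dic, ta, T, S, k)


def saturation_state(CO3: float, S: float, Ksp: float) -> float:
    """Saturation state Omega = [Ca2+][CO3 2-]/Ksp.

    ``CO3`` in µmol kg-1; calcium taken proportional to salinity
    (Riley & Tongudai convention); ``Ksp`` in (mol kg-1)^2.
    """
    if CO3 <= 0:
        raise ValueError(f"CO3 must be positive, got {CO3}")
    ca = (0.02128 / 40.087) * (S / 1.80655)
    return ca * (CO3 * 1e-6) / Ksp
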