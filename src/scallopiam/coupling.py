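"""Couplings from seawater chemistry and temperature to scallop biology.

Three switchable pathways link the box model to the population model:

1. *Larval survival*: surface aragonite saturation state, lagged two years
   to the brood's spawning date, scales larval survival linearly
   (calibrated on king scallop data; 45% control survival). The scale
   factor multiplies spawning stock biomass before the stock-recruit curve.
2. *Temperature on growth*: the Brody coefficient K responds to 2-year
   lagged deep temperature through an Arrhenius law on the overall growth
   performance index.
3. *Acidification on growth*: a cross-species bivalve meta-analysis
   regression, dG = 1.272 dOmega + 0.075 (relative changes from control),
   converts the relative deep calcite saturation change into a relative
   change in K.

The two growth deltas combine additively: K_eff = K + dK_T + dK_Omega.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "CouplingParams",
    "larval_survival_scale",
    "oa_growth_delta",
    "temperature_growth_delta",
    "effective_K",
]

R_GAS = 8.314462618          # J mol-1 K-1
K_FLOOR = 1e-3               # yr-1, floor when deltas would drive K negative
LAG_YEARS = 2


@dataclass(frozen=True)
class CouplingParams:
    """Coupling coefficients and references.

    ``omega_control`` / ``T_ref`` are the region's first-simulated-year
    annual means of deep calcite saturation and deep temperature (the
    experimental "control" conditions are not pinned to a calendar year in
    the source meta-analyses). ``Ea`` is the activation energy of the
    Arrhenius temperature-growth law (J mol-1); 90 kJ/mol sits in the upper
    range of ectotherm growth activation energies (Q10 ~ 3.4 at 10 degC)
    and reflects the strong thermal sensitivity of scallop growth
    performance across latitudes.
    """

    survival_slope: float = 20.5       # % survival per Omega_ar unit
    survival_offset: float = 3.7       # %
    control_survival: float = 45.0     # %
    growth_slope: float = 1.272        # relative dG per relative dOmega
    growth_intercept: float = 0.075
    omega_control: float = 1.0         # region deep Omega_ca reference
    T_ref: float = 10.0                # degC, region lagged deep-T reference
    Ea: float = 90_000.0               # J mol-1
    lag: int = LAG_YEARS
    zero_at_control: bool = False      # re-zero the regression at dOmega = 0
    enable_OA_recruitment: bool = True
    enable_OA_growth: bool = True
    enable_T_growth: bool = True

    def __post_init__(self) -> None:
        if self.lag != LAG_YEARS:
            raise ValueError("the recruitment/growth lag is fixed at 2 years")


def larval_survival_scale(omega_ar_lag2: float, cp: CouplingParams) -> float:
    """Larval-survival scale factor from 2-year lagged surface Omega_ar.

    scale = (20.5 * Omega_ar - 3.7) / 45, floored at zero. Equals 1 at the
    control survival (Omega_ar ~ 2.376) and multiplies spawning stock
    biomass before the stock-recruit evaluation.
    """
    if omega_ar_lag2 <= 0:
        raise ValueError("omega_ar must be positive")
    if not cp.enable_OA_recruitment:
        return 1.0
    pct = cp.survival_slope * omega_ar_lag2 - cp.survival_offset
    return max(0.0, pct / cp.control_survival)


def oa_growth_delta(omega: float, cp: CouplingParams, K: float) -> float:
    """Change in K (yr-1) from the saturation-state growth regression.

    dOmega is the *relative* departure from the control saturation state;
    the regression intercept (+0.075 at dOmega = 0) is applied as printed
    unless ``zero_at_control`` is set.
    """
    if cp.omega_control <= 0:
        raise ValueError("omega_control must be positive")
    if not cp.enable_OA_growth:
        return 0.0
    d_omega = (omega - cp.omega_control) / cp.omega_control
    dG = cp.growth_slope * d_omega
    if not cp.zero_at_control:
        dG += cp.growth_intercept
    return K * dG


def temperature_growth_delta(T_lag2: float, cp: CouplingParams, K: float) -> float:
    """Change in K (yr-1) from 2-year lagged deep temperature (Arrhenius).

    dK_T = K * (exp(-Ea/R (1/T - 1/T_ref)) - 1) with absolute temperatures;
    zero at the reference, positive for warming (the modeled temperatures
    stay below the species' tolerated maximum).
    """
    if not cp.enable_T_growth:
        return 0.0
    TK = T_lag2 + 273.15
    TrefK = cp.T_ref + 273.15
    return K * (math.exp(-cp.Ea / R_GAS * (1.0 / TK - 1.0 / TrefK)) - 1.0)


def effective_K(K: float, dK_T: float, dK_omega: float) -> float:
    """Additive combination K_eff = K + dK_T + dK_Omega, floored at epsilon."""
    k = K + dK_T + dK_omega
    if k <= 0:
        warnings.warn(
            f"effective K {k:.4g} yr-1 non-positive; floored at {K_FLOOR}",
            RuntimeWarning, stacklevel=2,
        )
        return K_FLOOR
    return k
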