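"""Size-structured sea scallop population dynamics.

Abundance is tracked in 5-mm shell-height bins from 40 mm to a plus-group at
>= 180 mm, separately for Georges Bank (GB) and the Mid-Atlantic Bight (MA).
Individuals grow by a von Bertalanffy increment discretized into a
column-stochastic growth transition matrix (rebuilt whenever the effective
Brody coefficient changes), die from natural, fishing, incidental and
discard mortality applied as simultaneous instantaneous rates (Baranov
accounting), and recruit at age 2 through a Beverton-Holt stock-recruit
relationship with lognormal AR(1) deviates.

Units: abundance in millions of individuals, shell height in mm, meat
weight in g, biomass in metric tons (mT) of meats. With abundance in
millions and meat weight in grams, summed products are directly mT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ScallopParams",
    "SizeGrid",
    "PopulationState",
    "GrowthMatrix",
    "CatchAtSize",
    "build_growth_matrix",
    "selectivity",
    "meat_weight",
    "market_split",
    "spawning_biomass",
    "exploitable_abundance",
    "exploitable_biomass",
    "recruitment",
    "step_population",
    "allocate_catch",
    "solve_annual_fishing_mortality",
]

DT = 0.1
LB_PER_KG = 2.2046226218
GRAMS_PER_LB = 453.592
MT_PER_MLB = 453.5924     # 1 million lb in mT

MARKET_CLASSES = ("U10", "11-20", "21-30", "31-40")


@dataclass(frozen=True)
class ScallopParams:
    """Growth, selectivity, weight, mortality and recruitment parameters."""

    region: str
    H_inf: float            # mm, asymptotic shell height
    sigma_H_inf: float      # mm, between-individual SD of H_inf
    K: float                # yr-1, Brody growth coefficient
    sigma_K: float          # yr-1
    a_L: float              # logistic selectivity intercept
    b_L: float              # logistic selectivity slope (mm-1)
    a_mw: float             # shell-height/meat-weight, ln-scale intercept
    b_mw: float             # allometric exponent
    MW_inf: float           # g, printed meat weight at H_inf
    M: float                # yr-1, natural mortality
    I: float                # yr-1, incidental mortality scale
    D: float                # discard mortality fraction
    ln_aR: float            # Beverton-Holt asymptote, ln individuals
    sigma_ln_aR: float
    ln_gammaR: float        # Beverton-Holt half-saturation, ln mT
    sigma_ln_gammaR: float
    rho: float              # recruitment deviate AR(1) autocorrelation
    F_msy: float            # yr-1
    F_abc: float            # yr-1

    def __post_init__(self) -> None:
        if self.H_inf <= 90:
            raise ValueError("H_inf must exceed the 90 mm exploitable size")
        if not 0 < self.K < 1:
            raise ValueError("K must lie in (0, 1) yr-1")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.F_abc > self.F_msy:
            raise ValueError("F_abc must not exceed F_msy")


@dataclass(frozen=True)
class SizeGrid:
    """Contiguous 5-mm shell-height bins with an absorbing plus-group."""

    lower: np.ndarray = field(default_factory=lambda: np.arange(40.0, 185.0, 5.0))
    width: float = 5.0

    @property
    def n(self) -> int:
        return self.lower.size

    @property
    def mid(self) -> np.ndarray:
        return self.lower + self.width / 2.0

    @property
    def edges(self) -> np.ndarray:
        """Bin edges; the last bin (plus-group) is open above."""
        return np.append(self.lower, self.lower[-1] + self.width)


DEFAULT_GRID = SizeGrid()


@dataclass
class PopulationState:
    """Abundance vector plus the recruitment machinery for one region.

    ``pending_recruits`` is the 2-year pipeline: index 0 enters the 40-mm
    bin at the next annual boundary, index 1 the year after.
    """

    region: str
    N: np.ndarray                    # millions per bin
    eps_prev: float = 0.0            # AR(1) recruitment deviate memory
    pending_recruits: list = field(default_factory=lambda: [0.0, 0.0])

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        if np.any(self.N < 0):
            raise ValueError("abundance must be non-negative")
        if len(self.pending_recruits) != 2:
            raise ValueError("recruit pipeline must hold exactly 2 years")


@dataclass(frozen=True)
class GrowthMatrix:
    """Column-stochastic size-transition matrix for one sub-annual step."""

    P: np.ndarray
    K_eff: float
    dt: float

    def __post_init__(self) -> None:
        colsums = self.P.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("growth matrix columns must sum to 1")
        if np.triu(self.P, 1).max(initial=0.0) > 1e-12:
            raise ValueError("growth matrix must not shrink individuals")


@dataclass
class CatchAtSize:
    """Landed catch for one region and step: numbers, weight, market split."""

    region: str
    numbers: np.ndarray          # millions per bin
    weight_mT: np.ndarray        # mT meats per bin
    category_fractions: dict     # weight-based, sums to 1 when catch > 0
    empty: bool = False


# ---------------------------------------------------------------------------
# growth

_GH_NODES = 15


def _hermite(mean: float, sd: float, n: int = _GH_NODES):
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return mean + sd * x, w / w.sum()


def build_growth_matrix(K_eff: float, p: ScallopParams,
                        grid: SizeGrid = DEFAULT_GRID,
                        dt: float = DT) -> GrowthMatrix:
    """Growth transition matrix from the von Bertalanffy increment.

    The per-step increment dH = (H_inf - H)(1 - exp(-K dt)) is integrated
    over the between-individual distribution of (H_inf, K) -- independent
    Gaussian with the printed standard deviations, K floored at zero and
    scaled multiplicatively by K_eff/K so the relative dispersion is
    preserved and K_eff -> 0 recovers the no-growth identity -- and exactly
    over shell height uniform within each source bin. For a fixed (H_inf, K)
    the destination is piecewise linear and monotone in the within-bin
    position, so the mass below each bin edge is obtained by inverting that
    map; without the within-bin integration, advancement probabilities
    collapse whenever the per-step increment is small against the 5-mm bin
    width. Destinations beyond the plus-group accumulate there, so each
    column sums to 1.
    """
    if K_eff <= 0:
        raise ValueError(f"K_eff must be positive, got {K_eff}")
    hs, hw = _hermite(p.H_inf, p.sigma_H_inf)
    ks, kw = _hermite(p.K, p.sigma_K)
    ks = np.maximum(ks, 0.0) * (K_eff / p.K)
    g = 1.0 - np.exp(-ks * dt)                        # growth fraction per K node
    edges = grid.edges
    n = grid.n
    w = grid.width
    wts = np.outer(hw, kw).ravel()                    # (H_inf, K) node weights
    hinf = np.repeat(hs, ks.size)
    gf = np.tile(g, hs.size)
    P = np.zeros((n, n))
    for j, lo in enumerate(grid.lower):
        if j == n - 1:
            P[j, j] = 1.0                             # plus-group absorbing
            continue
        # u* solving dest(u*) = E: growing branch (u < H_inf) has
        # dest = u(1-g) + H_inf*g; flat branch (u >= H_inf) has dest = u
        E = edges[j + 1:n][None, :]                   # upper edges of bins j..n-2
        u_star = np.where(E <= hinf[:, None],
                          (E - hinf[:, None] * gf[:, None])
                          / (1.0 - gf[:, None]),
                          E)
        cum = np.clip((u_star - lo) / w, 0.0, 1.0)    # P(dest <= E) given node
        cum = np.concatenate([cum, np.ones((cum.shape[0], 1))], axis=1)
        mass = np.diff(cum, prepend=0.0, axis=1)      # per destination bin
        P[j:, j] = wts @ mass
    P /= P.sum(axis=0, keepdims=True)
    return GrowthMatrix(P=P, K_eff=K_eff, dt=dt)


# ---------------------------------------------------------------------------
# per-size relationships

def selectivity(H, p: ScallopParams, domed: bool = False,
                dome_mid: float = 140.0, dome_slope: float = 0.1):
    """Logistic gear selectivity s(H) = 1 / (1 + exp(a_L - b_L H)).

    ``domed=True`` multiplies by a descending logistic limb (used to mimic
    large scallops protected inside closed areas, as in the GB 2001-2003
    assessment configuration).
    """
    H = np.asarray(H, dtype=float)
    s = 1.0 / (1.0 + np.exp(p.a_L - p.b_L * H))
    if domed:
        s = s / (1.0 + np.exp(dome_slope * (H - dome_mid)))
    return s if s.ndim else float(s)


def meat_weight(H, p: ScallopParams):
    """Allometric shell-height/meat-weight: MW = exp(a_mw + b_mw ln H), grams."""
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0):
        raise ValueError("shell height must be positive")
    mw = np.exp(p.a_mw + p.b_mw * np.log(H))
    return mw if mw.ndim else float(mw)


def market_split(weight_mT: np.ndarray, p: ScallopParams,
                 grid: SizeGrid = DEFAULT_GRID) -> tuple[dict, bool]:
    """Weight-based market-category fractions of a catch-at-size vector.

    Meat count per pound = 453.592 / MW(H); counts of 10 or fewer are U10,
    then 11-20, 21-30, and 31-40, with anything smaller (count > 40) folded
    into 31-40. Zero catch returns zero fractions and an ``empty`` flag.
    """
    total = float(weight_mT.sum())
    if total <= 0:
        return {c: 0.0 for c in MARKET_CLASSES}, True
    counts = GRAMS_PER_LB / meat_weight(grid.mid, p)
    frac = {c: 0.0 for c in MARKET_CLASSES}
    for w, cnt in zip(weight_mT, counts):
        if cnt <= 10.0:
            frac["U10"] += w
        elif cnt <= 20.0:
            frac["11-20"] += w
        elif cnt <= 30.0:
            frac["21-30"] += w
        else:
            frac["31-40"] += w
    return {c: v / total for c, v in frac.items()}, False


def spawning_biomass(state: PopulationState, p: ScallopParams,
                     grid: SizeGrid = DEFAULT_GRID) -> float:
    """Whole-stock meat biomass (mT) of everything on the grid (>40 mm)."""
    return float(np.sum(state.N * meat_weight(grid.mid, p)))


def exploitable_abundance(state: PopulationState,
                          grid: SizeGrid = DEFAULT_GRID) -> float:
    """Millions of individuals in bins above 90 mm shell height."""
    return float(state.N[grid.lower >= 90.0].sum())


def exploitable_biomass(state: PopulationState, p: ScallopParams,
                        grid: SizeGrid = DEFAULT_GRID) -> float:
    """Meat biomass (mT) in bins above 90 mm shell height."""
    mask = grid.lower >= 90.0
    return float(np.sum(state.N[mask] * meat_weight(grid.mid[mask], p)))


# ---------------------------------------------------------------------------
# recruitment

def beverton_holt(S_eff: float, p: ScallopParams) -> float:
    """Deterministic Beverton-Holt recruitment (millions) at spawning biomass S_eff (mT).

    The asymptote exp(ln_aR) is in individuals (Table-scale recruitment of
    hundreds of millions); the half-saturation exp(ln_gammaR) in mT meats.
    """
    if S_eff < 0:
        raise ValueError("spawning biomass must be non-negative")
    a_R = math.exp(p.ln_aR) / 1e6          # millions
    gamma_R = math.exp(p.ln_gammaR)        # mT
    return a_R * S_eff / (gamma_R + S_eff)


def recruitment(S_eff: float, p: ScallopParams, eps_prev: float,
                rng: np.random.Generator) -> tuple[float, float]:
    """Stochastic recruitment (millions) and the updated AR(1) deviate.

    eps_t = rho * eps_{t-1} + sqrt(1 - rho^2) * eta, eta ~ N(0, sigma);
    the lognormal multiplier exp(eps - sigma^2/2) has unit mean.
    """
    sigma = p.sigma_ln_aR
    eps = p.rho * eps_prev + math.sqrt(1.0 - p.rho ** 2) * rng.normal(0.0, sigma)
    mult = math.exp(eps - sigma ** 2 / 2.0)
    return beverton_holt(S_eff, p) * mult, eps


# ---------------------------------------------------------------------------
# mortality, catch, projection

def total_mortality(F_t: float, p: ScallopParams, grid: SizeGrid = DEFAULT_GRID,
                    domed: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin instantaneous total mortality Z and its landed component F*s.

    Z = M + s(H) F + I F/F_msy + D F s_asc(H)(1 - s(H)): incidental
    mortality scales with fishing intensity relative to F_msy; discard
    mortality acts on sizes the gear contacts but does not retain.
    """
    if F_t < 0:
        raise ValueError("fishing mortality must be non-negative")
    s = selectivity(grid.mid, p, domed=domed)
    s_asc = selectivity(grid.mid, p, domed=False)
    F_land = s * F_t
    Z = p.M + F_land + p.I * F_t / p.F_msy + p.D * F_t * s_asc * (1.0 - s)
    return Z, F_land


def step_population(state: PopulationState, G: GrowthMatrix, F_t: float,
                    p: ScallopParams, dt: float = DT,
                    recruits_in: float = 0.0, domed: bool = False
                    ) -> tuple[PopulationState, CatchAtSize]:
    """One sub-annual step: mortality and catch, then growth, then recruits.

    Landed catch follows the Baranov apportionment
    C_i = (F s_i / Z_i)(1 - exp(-Z_i dt)) N_i; survivors are redistributed
    by the growth matrix; ``recruits_in`` (millions) enters the 40-mm bin.
    """
    grid = DEFAULT_GRID
    Z, F_land = total_mortality(F_t, p, grid, domed=domed)
    decay = np.exp(-Z * dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        catch_n = np.where(Z > 0, F_land / Z * (1.0 - decay) * state.N, 0.0)
    survivors = state.N * decay
    N_next = G.P @ survivors
    N_next[0] += recruits_in
    if np.any(N_next < -1e-9):
        raise RuntimeError("negative abundance produced by population step")
    N_next = np.maximum(N_next, 0.0)

    w = catch_n * meat_weight(grid.mid, p)
    fracs, empty = market_split(w, p, grid)
    new_state = PopulationState(region=state.region, N=N_next,
                                eps_prev=state.eps_prev,
                                pending_recruits=list(state.pending_recruits))
    return new_state, CatchAtSize(region=state.region, numbers=catch_n,
                                  weight_mT=w, category_fractions=fracs,
                                  empty=empty)


def allocate_catch(Q_t: float, states: dict, params: dict) -> dict:
    """Split a fleet-wide quota across regions by exploitable biomass share."""
    if Q_t < 0:
        raise ValueError("quota must be non-negative")
    shares = {r: exploitable_biomass(s, params[r]) for r, s in states.items()}
    total = sum(shares.values())
    if total <= 0:
        if Q_t > 0:
            raise RuntimeError("cannot allocate positive quota with no exploitable biomass")
        return {r: 0.0 for r in states}
    return {r: Q_t * v / total for r, v in shares.items()}


def project_annual_catch(state: PopulationState, matrices: list, F_t: float,
                         p: ScallopParams, recruits_in: float = 0.0,
                         domed: bool = False) -> tuple[PopulationState, float]:
    """Project one year (10 steps) at constant F; return final state and landed mT."""
    s = state
    total = 0.0
    for i, G in enumerate(matrices):
        s, c = step_population(s, G, F_t, p, recruits_in=recruits_in if i == 0 else 0.0,
                               domed=domed)
        total += float(c.weight_mT.sum())
    return s, total


F_SOLVE_MAX = 4.0


def solve_annual_fishing_mortality(state: PopulationState, matrices: list,
                                   quota_mT: float, p: ScallopParams,
                                   recruits_in: float = 0.0,
                                   domed: bool = False) -> float:
    """Annual F whose projected landed biomass meets ``quota_mT``.

    Bracketed solve on [0, 4 yr-1]; if even the upper bound cannot land the
    quota (stock too small) the upper bound is returned and the quota is
    simply not achieved.
    """
    if quota_mT <= 0:
        return 0.0

    def gap(F):
        return project_annual_catch(state, matrices, F, p,
                                    recruits_in=recruits_in, domed=domed)[1] - quota_mT

    if gap(F_SOLVE_MAX) < 0:
        return F_SOLVE_MAX
    return float(brentq(gap, 0.0, F_SOLVE_MAX, xtol=1e-6))
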