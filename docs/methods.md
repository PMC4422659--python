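# Methods

This note documents the model equations as implemented, the defaults and
their units, the numerical choices, what the synthetic generators emulate,
and the known limitations. Parameter values come from the published
parameter and initial-condition tables of the source study; a provenance
map (`scallopiam.defaults.PROVENANCE`) ties every packaged numeric to its
table.

## Carbonate system (`carbonate`)

The CO₂ system is solved from (DIC, TA) or (TA, pCO₂) at surface pressure
on the total pH scale. Constants dialect: K1/K2 from Lueker, Dickson &
Keeling (2000); KB Dickson (1990b); KW Millero (1995, SWS→total); KSO₄
Dickson (1990a); KF Dickson & Riley (1979); K0 Weiss (1974); calcite and
aragonite solubilities Mucci (1983); total boron Uppström (1974); calcium
proportional to salinity (Riley & Tongudai). The source study delegates to
the CO2SYS software without stating its option set; this dialect is
CO2SYS's historical default and is recorded in `ConstantsDialect`.
Nutrient alkalinity is omitted (the box model carries DIC/TA only).

The alkalinity balance includes carbonate, borate, water, free-H, bisulfate
and fluoride terms and is solved by Brent's method on pH ∈ (3, 12) to
1e-10 pH (alkalinity residual < 1e-3 µmol/kg). Each equilibrium constant
reproduces its published check value at S = 35, 25 °C to the printed
precision; the (DIC, TA) → pCO₂ → DIC round trip closes to < 0.01 µmol/kg
across the shelf envelope. Valid ranges: T ∈ [−2, 40] °C (the winter
Mid-Atlantic climatology dips below 0 °C), S ∈ [20, 40].

## Two-box biogeochemistry (`boxmodel`)

Per region, a surface box (h₁ = 22/25 m for MA/GB) over a deep box
(h₂ = 38/45 m). Forcing follows
X(t) = X̄ + A·sin(2π(t + φ)) with t in decimal years — the fitted means,
amplitudes and phases are taken as printed. The printed phases do not
recover a consistent calendar alignment across regions and variables (the
supplementary relaxation terms τ, which likely carry part of the phase
information, are not recoverable from the main text; they are stored in
config but unused). Annual-mean quantities, which all of the reported
endpoints are, are insensitive to the phase convention; sub-annual
covariances (e.g. bloom timing vs stratification) are not, and this is the
main structural uncertainty of the module.

Processes, per Δt = 0.1 yr Euler step:

- **Gas exchange**: F = k_w K₀ (pCO₂ᵃᵗᵐ − pCO₂ˢᵉᵃ) with
  k_w = 0.251·U²·(Sc/660)^(−1/2) cm/hr (quadratic wind, Wanninkhof-type
  coefficient; Schmidt-number polynomial for seawater CO₂), U² the
  climatological mean-square wind.
- **Biology**: export production F_ratio·PP leaves the surface box; a
  fraction *Remin* is remineralized in the deep box. CaCO₃ production
  PICPOC·PP removes DIC and 2× TA from the surface; all exported CaCO₃
  redissolves at depth. With Remin < 1 (GB) the column is a net sink,
  balanced at the periodic steady state by a ~30 µatm surface
  undersaturation — mechanistically reproducing the study's note that its
  modeled surface pCO₂ ran ~30 ppm below observations. Unit conversions
  use 12.011 g/mol and ρ = 1025 kg/m³.
- **Mixing**: exchange velocity v = K_s/((h₁+h₂)/2) applied to DIC/TA
  gradients; conserves column inventories exactly. When the prescribed
  T/S make the column statically unstable (UNESCO 1983 surface-pressure
  density), the tracers homogenize within the step (winter convection).
- **Warming**: scenario SST ramps linearly from 0 at 2000 to the scenario
  total (default 1.4 °C for RCP8.5) at 2050, applied to both boxes'
  climatological means.

The system locks to a periodic steady state within ~5 years of the printed
initial conditions (surface pH drift < 1e-4/decade thereafter).

## Population model (`population`)

5-mm bins, 40→180 mm plus an absorbing plus-group; abundance in millions
(so abundance × meat weight in g = biomass in mT).

**Growth.** Per step, the increment ΔH = (H∞ − H)(1 − e^(−K_eff·dt)) is
integrated over independent Gaussian between-individual (H∞, K) with the
printed SDs (Gauss–Hermite, 15 nodes each; K floored at 0 and scaled
multiplicatively by K_eff/K̄ so the relative dispersion is preserved and
K_eff → 0 gives the identity), and *exactly* over shell height uniform
within the source bin: for fixed (H∞, K) the destination is piecewise
linear in the within-bin position, so bin masses follow from inverting
that map. Without the within-bin integration, advancement probabilities
collapse once the per-step increment is small against the bin width and
no scallop ever reaches the premium sizes. The matrix is column-stochastic
and shrinkage-free by construction and matches a 4×10⁵-individual Monte
Carlo oracle to < 0.01 mm in mean binned increment.

**Mortality and catch.** Z(H) = M + s(H)·F + I·F/F_msy +
D·F·s(H)(1 − s(H)) with logistic selectivity s(H) = 1/(1+e^(a_L−b_L·H))
(an optional domed variant mimics the GB 2001–2003 closed-area
configuration). The application formulas for incidental (I) and discard
(D) mortality are not printed in the source; the scalings above
(incidental proportional to fishing intensity, discards on
contacted-but-unretained sizes) are this package's documented choice and
are configurable. Landed catch uses the Baranov apportionment
(F·s/Z)(1 − e^(−Z·dt))·N. Market categories follow meat count
453.592/MW(H) per lb: ≤10 U10, ≤20, ≤30, else 31–40.

**Recruitment.** R = a_R·S_eff/(γ_R + S_eff); a_R = e^(ln a_R) is read in
*individuals* (the millions reading is off by 10⁶ and contradicts the
study's own halved-survival example), γ_R = e^(ln γ_R) mT. Deviates:
ε_t = ρ ε_{t−1} + √(1−ρ²)·N(0, σ), multiplier e^(ε−σ²/2) (unit mean);
σ is taken as the printed σ_ln a_R per region, the only printed
recruitment dispersion. Spawning occurs once per model year; the larval
survival scale (surface Ω_ar, lagged 2 yr) multiplies spawning biomass
before the curve; recruits enter the 40-mm bin two years after spawning.

**Initial state.** The year-2000 survey size composition is not printed;
a synthetic lognormal shell-height shape (mode 85 mm) is tilted per region
so that the printed abundances (3129/3523 million GB/MA) and total biomass
(172.458 Mlb) are matched exactly, with biomass split in proportion to
abundance (configurable).

## Environmental couplings (`coupling`)

- Larval survival: scale = (20.5·Ω_ar − 3.7)/45, floored at 0; surface
  box, 2-yr lag.
- Acidification on growth: ΔK_Ω = K·(1.272·ΔΩ + 0.075) with ΔΩ the
  *relative* change of deep Ω_ca from the control; the regression's
  intercept is applied as printed (a `zero_at_control` flag provides the
  re-zeroed variant). Control Ω and reference T are the first simulated
  year's annual means (the underlying experiments' controls are not tied
  to a calendar year).
- Temperature on growth: ΔK_T = K·(e^(−Ea/R·(1/T−1/T_ref)) − 1) on
  2-yr-lagged deep temperature. The cited allometric study's constants are
  not printed; Ea defaults to 90 kJ/mol (upper range of ectotherm growth
  activation energies, Q₁₀ ≈ 3.4 at 10 °C), consistent with warming
  initially outweighing acidification until ~2030 as the source describes;
  it is a named config constant.
- Combination is additive: K_T,Ω = K + ΔK_T + ΔK_Ω, floored at 10⁻³ yr⁻¹
  with a warning. All three pathways switch off independently, and with
  all switches off a scenario run is bit-identical to the control at the
  same seed.

## Economics (`economics`)

Equations as printed: C = w·(Q/(e^A BIO^α))^(1/β) (= w·DAS on the
production surface), MC = ∂C/∂Q, MCI = 0.95·P̄·0.52 − MC, MR = P̄ with P̄
the landings-weighted mean category price, D_t = D_{t−1}(1 + e_p·r_p +
e_i·r_i). A = −9.95 is the log-scale intercept: that reading reproduces
the printed year-2000 landings from the printed biomass and effort within
1.1%; the linear reading is off by orders of magnitude.

Surrogates for unprinted supplementary relationships (each flagged and
configurable): DAS_max inverts the production function at Q_ABC; daily
cost w_t = w₀(1 − φ_fuel + φ_fuel·FUEL_t/FUEL₀) with fuel share 0.3 and
fuel growing at 1.1 %/yr; prices follow ln P_i = c_i + 0.3·ln IP +
0.5·ln PCDI with intercepts calibrated to the printed year-2000 prices;
F_das = F₀/DAS₀ with F₀ = −ln(1 − LAND₀/BIO₀). Optimization is a
1000-point DAS grid with bounded scalar refinement, ties toward smaller
effort; it matches a 10⁴-point brute-force search within one grid cell on
randomized instances.

## Simulator (`simulator`)

The biogeochemistry is integrated first over the whole horizon and used as
forcing (one-way coupling, as in the source design). Each model year:
management (Q_ABC at F_ABC, DAS cap) → fleet optimum → realization of the
chosen catch by one fleet-wide annual F solved (bracketed, [0, 4] yr⁻¹) so
combined landings meet Q_t — the exploitable-biomass proportionality is
retained as the regional quota bookkeeping. Solving separate per-region Fs
against those quotas instead drives the Mid-Atlantic into an effort spiral
(F → 1 yr⁻¹), because the printed MA selectivity midpoint (111.5 mm) sits
high against its 132-mm asymptotic size; the single-fleet-F reading matches
the source's single F_t (its Eq 7) and reproduces its reported hindcast
means. Sub-annual order is mortality-then-growth; recruits enter at the
first step of their maturity year. Ensemble seeds derive from
SHA-256(master, run-index), so paired scenario ensembles share recruitment
deviates exactly.

Hindcast mode (2000–2012) replaces stochastic recruitment and economic
drivers with forcing series; beyond 2012 the run switches to stochastic
recruitment and scenario-constant growth rates (income +2 %/yr by
default).

## Synthetic forcing (`synthetic`)

Stand-ins for the assessment and economic series used by the original
hindcast: income grows at 2 %/yr with 0.5% step noise; import prices are
AR(1) (ρ = 0.6, σ = 8%) around the printed year-2000 mean; exports
constant; fuel at the printed 1.1 %/yr. Recruitment is AR(1)-lognormal
(printed ρ and σ_ln a_R) around the printed year-2000 assessment
recruitment (3728 million, split by regional Beverton–Holt share) —
the hindcast decade was a documented recruitment boom far above the
fitted stock–recruit mean, and that boom, not the curve, drove the
biomass trajectory the hindcast emulates; a `stock_recruit` mode anchors
at the curve instead. The generator does not emulate the real series'
business-cycle structure (e.g. the 2008 income dip) or observed
recruitment autocorrelation beyond AR(1), so hindcast agreement
demonstrates mechanistic scale fidelity, not event-level skill.

## Sensitivity (`sensitivity`)

Normal draws per parameter (printed SDs for growth/recruitment, 5%
relative for mortalities and selectivity, 2% for production-function
coefficients; the original 38-parameter distribution table is unpublished,
so the design is config-driven). Responses are the 2012 biomass, landings
and revenue under fixed forcing. Forward stepwise OLS on standardized
predictors with entry p = 0.05; zero-variance designs and singular
candidate matrices are rejected with named culprits; failed runs are
recorded with their exception.

## Numerical/problem sizes used in the shipped checks

Box-model runs: 1–51 years at 10 steps/yr. Hindcast: 13 years. Scenario
ensembles in tests: 4 members to 2050 per scenario (the library default is
100, matching the source's forecast ensembles; a 2×100-member paired
experiment completes in a few minutes on one core). Monte Carlo test
experiment: 10 iterations (library default 500).

## Known limitations

- The deep boxes are more corrosive than the source's projections: with
  the printed export/remineralization/diffusivity parameters, seasonal
  remineralized DIC accumulates under stratification (40–80 µmol/kg), so
  annual-mean deep pH sits ~0.1 below the surface, while the source
  reports deep ≈ surface pH. Its supplementary relaxation (τ) terms —
  unrecoverable from the main text — plausibly ventilated its deep boxes.
  The corresponding 2050 deep endpoints are deliberately left failing in
  the acceptance suite rather than re-tuned; the deep chemistry produced
  here is consistent with observed shelf bottom waters.
- The first-year Mid-Atlantic surface mean pH is 8.11 against a reported
  8.05: the printed initial DIC/TA are ~50 µatm undersaturated against
  the year-2000 atmosphere under any standard constants dialect, so 8.05
  appears to describe the source model's post-spin-up state (ours: 8.09).
- Phases of the seasonal forcing are taken as printed but cannot be given
  a consistent calendar interpretation (see above).
- No rotational/closed-area management, no horizontal exchange between
  regions, no temperature effect on recruitment, additive (never
  synergistic) T×Ω interaction — all structural choices inherited from
  the source design.
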