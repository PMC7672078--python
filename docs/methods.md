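# Methods

## The model

`soilmend` implements a microbial-enzyme decomposition model of soil organic
carbon (SOC) with explicit microbial dormancy.  Ten pools are tracked in
mg C cm⁻³ soil: oxidatively and hydrolytically degradable particulate carbon
(P1, P2), mineral-associated carbon (M), dissolved organic carbon (D), DOC
adsorbed to the mineral phase (Q), active and dormant microbial biomass
(BA, BD), and three extracellular enzyme pools (EP1, EP2, EM) that
respectively decompose P1, P2 and M.  An eleventh state variable accumulates
respired CO₂.

Fluxes (all h⁻¹-scaled, assembled in `mend_core.compute_fluxes`):

- **Decomposition** of P1, P2, M is Michaelis–Menten in the substrate and
  first-order in the corresponding enzyme pool:
  `F = V·E·S/(K + S)`.
- **Microbial uptake** of DOC is `F1 = (1/Yg_T)·(Vg_T + Vmt_T)·S·BA` with
  saturation `S = D/(KD_T + D)`; carbon not retained as growth
  (`(1 − Yg_T)·F1`) is growth respiration.  Gross growth is `Vg_T·S·BA`,
  active maintenance `Vmt_T·S·BA`.
- **Dormancy** transitions are gated by substrate saturation:
  `BA → BD` at `(1 − S)·Vmt_T`, reactivation `BD → BA` at `S·Vmt_T`;
  dormant cells respire maintenance at the reduced rate `β·Vmt_T`.
- **Sorption** of DOC is Langmuir-type: adsorption
  `Kads·D·(1 − Q/Qmax)`, desorption `Kdes·Q/Qmax`.
- **Mortality** `rM·BA` splits between DOC (fraction `gD`) and P2; enzyme
  production is first-order in BA (`pEP1, pEP2, pEM`) and enzyme turnover
  (`rE`) returns enzyme carbon to DOC.

Temperature enters three ways: all maximum rates (V-type, including Vg and
Vmt) scale by an Arrhenius factor with activation energy `Ea_V`; all
half-saturation constants by `Ea_K`; sorption rate constants by `Ea_ads`;
and the intrinsic carbon use efficiency declines linearly,
`Yg(T) = Yg + kYg·(T − 20 °C)` with `kYg = −0.01 °C⁻¹`, clipped to
(0.001, 0.999) purely for numerical safety (the clip is never active in the
−10…40 °C range).

The derivative assembly conserves carbon *exactly*: the sum of all pool
derivatives plus the CO₂ rate equals the external input for every state and
parameter set (a structural identity, tested to 10⁻¹² relative, and to
10⁻⁶ relative along integrated trajectories at the default solver
tolerances, rtol 10⁻⁸).

The maintenance–growth link is parameterized by the ratio
`α = Vmt/(Vg + Vmt)`, so `Vmt = α·Vg/(1 − α)`.

## Calibrated and fixed parameters

Five microbial parameters are calibrated: the initial active fraction `r0`,
maximum specific growth rate `Vg` (h⁻¹), the maintenance ratio `α`, the DOC
half-saturation constant `KD` (mg C cm⁻³), and the intrinsic carbon use
efficiency `Yg` at 20 °C.  Search bounds: `r0` ∈ [0.01, 1], `Vg` ∈
[0.001, 0.2], `α` ∈ [0.01, 0.6], `KD` ∈ [10⁻⁴, 0.5], `Yg` ∈ [0.1, 0.7].

All other constants ship as a versioned YAML fixture
(`soilmend/data/mend_defaults.yaml`) and are overridable from config.  The
defaults were set from the model-family literature and then fixed once
against three qualitative anchors of the default model: a realistic steady
pool composition under a 5 %-of-SOC annual input (SOC ≈ 21 mg C cm⁻³ with
roughly half mineral-associated, a third particulate, ~1.5 % biomass), a
steady-state warming response whose sign change sits near Yg ≈ 0.32, and
five-decade projections of a few percent magnitude.  Two defaults deserve
comment:

- `beta = 0.001` (dormant maintenance at 0.1 % of the active rate).  This
  parameter controls how strongly warming shifts the steady substrate
  saturation S* and is therefore the main lever on *where* the warming
  response changes sign; values ≥ 0.01 push the sign change above the
  plausible Yg range entirely.
- `Ea_K = 10 kJ mol⁻¹` (half-saturation constants are weakly
  temperature-sensitive, consistent with binding enthalpies being much
  smaller than catalytic activation energies, `Ea_V = 47 kJ mol⁻¹`).

## Scenarios

**Incubation** (`simulate.run_incubation`): closed system (no inputs) at
22 °C.  The substrate pulse at t = 0 adds 1 % of total soil carbon to DOC
(glucose) or to P2 (cellulose).  Initial pools come from the measured soil:
POC split 1:2 between P1 and P2, Q as the active 1 % of MOC, biomass split
`BA = r0·MBC`, enzymes at 1.1, 1.1 and 1.4 × 10⁻³ mg C cm⁻³.  The CO₂
observable is the *mean efflux over the interval ending at each collection*
(`ΔCO₂cum/Δt`), matching flask-accumulation measurements; MBC is
instantaneous BA + BD.  Two named schedules reproduce the laboratory
campaign: the 6-day glucose design (CO₂ at 2–144 h, 7 collections; MBC at
24/72/144 h) and the 729-day cellulose design (18 CO₂ and 8 MBC
collections).

**Spin-up** (`simulate.spin_up`): constant forcing with annual input equal
to 5 % of the soil's carbon, split 0.4 : 0.4 : 0.2 into P1 : P2 : D (litter
is mostly particulate).  Chunked integration (100-year blocks, capped at
2,000 years) with a Newton polish of the algebraic steady state once
transients have decayed; convergence is max relative pool tendency
< 10⁻⁹ h⁻¹.

**Projection** (`simulate.project_warming`): from the spun-up state, 50
years at the baseline temperature and at baseline + ΔT with identical
inputs; the headline number is the percent difference of end-simulation SOC.
The sign-change analysis (`find_yg_sign_change`) instead compares *steady
states* at 20 and 25 °C, which is the limit the transient approaches.

## Calibration

The objective is `J = w1·J1 + (1 − w1)·J2` with `w1 = 0.5` by default.  MBC
always scores MARE (mean absolute relative error); CO₂ scores MARE for
series of ≤ 10 observations and `1 − R²` otherwise (R² is unreliable for
short series).  Satisfactory fits require MARE ≤ 0.5 and, where R² applies,
R² ≥ 0.6 (both inclusive).  Replicates are averaged before fitting.

The optimizer is SCE-UA (shuffled complex evolution): Latin-hypercube start
of `ngs·(2k+1)` points, rank-striped partition into complexes, competitive
simplex evolution (reflection, then contraction, then unconditional random
replacement), shuffling, and a convergence rule of < 10⁻⁴ relative
improvement over 10 shuffling loops.  Every evaluation is archived.  Failed
forward simulations score +∞ rather than aborting the search.  Objective
evaluations integrate at rtol 10⁻⁶ (the objective is insensitive at that
level and the optimizer runs thousands of forward simulations).

## Uncertainty

The feasible parameter region is bounded by the critical objective function
value `Jcr = Jopt·(1 + p/(n−p)·F(0.05; p, n−p))`, with `n` the total number
of fitted observations (CO₂ + MBC) and `p = 5`.  Because the feasible set
is a thin correlated ridge (Yg trades off against α and Vg almost
perfectly, with pairwise correlations ≈ ±1 near the optimum), the SCE
archive alone under-maps its extent; `uncertainty.map_feasible_region`
therefore augments the archive with covariance-adapted sampling (three
rounds of 150 candidates from a 2×-inflated Gaussian fitted to the current
feasible members).  Ensembles are compared per parameter with the
Kruskal–Wallis rank test, paired best-fit estimates with the paired t-test.

Parametric sensitivity uses the log–log index
`SI = |log₁₀|Y_hi| − log₁₀|Y_lo|| / |log₁₀|X_hi| − log₁₀|X_lo||` applied to
steady-state pools when one parameter is swept across its range.  The sweep
uses the *empirically observed* parameter ranges (`OBSERVED_PARAM_RANGES`)
rather than the full search box: at the box's low-`Vg` extreme growth
cannot offset mortality, biomass goes extinct and no steady state exists.
On the defaults the ranking for steady SOC is Yg > α > Vg ≫ KD ≈ r0 (r0
only sets initial conditions, so its steady-state sensitivity is exactly
zero); steady CO₂ efflux equals the input by conservation, so its
sensitivity to every parameter is zero — both are model statements, not
artifacts.

## Synthetic data

The generator emulates the three inputs the pipeline needs.

- **Soils**: total SOC uniform on 10–60 mg C cm⁻³; MBC 0.5–2 %, DOC
  0.2–0.6 %, MOC 40–70 % of SOC, the remainder POC; pools sum to SOC
  exactly.  The full design is 4 sites × 2 ecosystems × 2 substrates = 16
  cases, three replicates.
- **Incubation series**: forward simulation on the laboratory schedules
  with multiplicative lognormal noise of mean one, independent per
  replicate and collection (default CV 10 % for CO₂, 15 % for MBC;
  respiration and biomass are positive with roughly proportional errors).
  Truncations keep collections at or before a cutoff (6, 30, 90, 180, 360,
  480 days of the 729-day record).
- **Field-warming tables**: percent effects drawn per duration group from
  prescribed means and spreads (−4.8 ± 8.4 % for < 1 year, 1.4 ± 4.1 % for
  1–10 years, 2.8 ± 9.1 % for > 10 years, sized 10/73/66 = 149 rows so the
  count-weighted mean reproduces the overall +1.6 %), converted to
  control/warmed SOC pairs with controls uniform on 20–150 units and
  warming magnitudes on 1–5 °C.

What the generator does *not* emulate: temporal autocorrelation of
measurement error, between-replicate soil heterogeneity, drifting
incubation conditions, isotopic signals, and moisture effects.  Passing
recovery tests therefore demonstrates identifiability under well-behaved
noise, not robustness to structural error in real data.

## Scripted experiments and their outcomes

`experiments.recovery_study` draws 20 realistic truths
(from `OBSERVED_PARAM_RANGES`), simulates the 729-day cellulose schedule
with 5 % CO₂ / 10 % MBC noise (3 replicates), calibrates each with SCE
(2 complexes, ≤ 2,500 evaluations — converges in ~2,000), and maps COFI
regions.  Two structural identifiability limits of this design show up
reproducibly and are reported by the tests as measured:

- `Yg` is displaced along the Yg–α–Vg ridge by the noise floor
  (J ≈ 0.015–0.03 at the truth); its median absolute error sits around
  0.03–0.035.
- `r0` only influences the first hours of a record whose first collection
  is at day 1, so a ±10 % change in r0 moves J by ~0.001 — far below the
  noise floor — and its best-fit error is prior-range-scale (median ≈ 0.25)
  even though noise-free data identify it exactly.  The COFI intervals are
  correspondingly wide and honest (they cover the truth).

`experiments.duration_contrast` truncates one noisy 729-day dataset to 6
days and recalibrates: with n = 6 observations against p = 5 parameters the
F-quantile explodes (F(0.05; 5, 1) ≈ 230) and the objective flattens, so
the feasible intervals of KD and Yg are far wider than from the full
record — the duration-information effect the pipeline exists to quantify.

## Numerical choices

- LSODA with rtol 10⁻⁸/atol 10⁻¹¹ for reported trajectories; rtol 10⁻⁶
  inside the calibration objective.  Pools are clipped at zero inside the
  right-hand side so the adaptive solver may probe O(atol) negatives
  without creating carbon.
- Steady states are polished with a damped Newton solve and accepted only
  if non-negative with residual < 10⁻⁹ h⁻¹; uniqueness was probed by
  spinning up from different initial states.
- CSV I/O parses floats in round-trip mode so write→read is lossless.
- All stochastic components draw from `numpy` Generators seeded explicitly;
  identical seeds give bit-identical datasets, archives and ensembles.

## Known limitations

- The flux formulation is one member of the microbial-enzyme model family;
  all forms are centralized in `compute_fluxes` so variants can be swapped.
- The F-distribution construction of Jcr assumes an SSE-like objective;
  with MARE components the 95 % label is approximate (observed coverage of
  the truth across recovery trials ≈ 85–95 %).
- Constant annual input and step temperature changes only; no seasonal or
  diurnal forcing, no moisture or nitrogen coupling, no isotope tracking.
- The meta-analysis is an unweighted percent-change synthesis; an
  inverse-variance lnRR mode exists but no publication-bias diagnostics.
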