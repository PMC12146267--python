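# Methods

## Model

Biomass `X` (OD600) of each species grows at the sum of its per-substrate
specific rates, each of the Monod–logistic form

    mu_s = w_s * mu_max,s * S/(S + K_s) * K_i^n/(K_i^n + [NO2]^n) * (1 - X/X_m)

with time in hours and concentrations in mM. Assumptions:

- **Additivity.** Simultaneous electron acceptors contribute additively to
  growth; there is no diauxie or preference switching.
- **Logistic capacity.** `X_m` is fixed at t = 0 from the linear model
  `X_m = sum_s beta_s * S_s(0)` (OD per mM of initial substrate) and acts as
  a hard brake `(1 - X/X_m)`; there is no death term.
- **Nitrite inhibition.** The inhibition law is a non-competitive Hill term
  with a single `K_i` per step and exponent `n >= 1` (default 1). The form
  was an open modeling choice; a single-`K_i`, n = 1 term is the simplest
  law consistent with a half-inhibition constant, and `n` is exposed for
  steeper, near-threshold toxicity. Note that with n = 1 a culture retains
  >50% of its rate at any inhibitor level below `K_i`, so literal "complete
  inhibition" below `K_i` is outside this law's reach. The inhibition
  multiplier applies per step (every growth step of a species carries its
  species-level `K_i`); this is configurable per step.
- **Lumped NO.** Nitric oxide is never an explicit pool: NO2⁻ → NO → N2O is
  one step producing ½ mol N2O per mol NO2⁻. The NO-exchange topology
  (scenario B) re-weights that step's growth contribution (2.0 for the
  importer 3H11, 0.5 for the exporter R12) and activates 3H11's otherwise
  latent lumped step; scenario A carries no overrides.
- **Stoichiometry and conservation.** Pools are tracked per N atom for
  NO3⁻/NO2⁻ and per molecule for the 2-N species N2O/N2. Each growth step
  consumes substrate at `q = mu * X / Y` with yield `Y`; non-growth
  conversions (R12's NO3⁻ → NO2⁻) run at `v_max * S/(S + K_m) * X` with zero
  growth. The right-hand side satisfies
  `d(NO3 + NO2 + 2 N2O + 2 N2)/dt = 0` identically, which every simulated
  trajectory inherits to integrator tolerance.
- **Yields vs capacity coefficients.** Yields default to the capacity betas
  (one number predicts both drawdown and maximum OD). The two are separable
  per substrate because they can genuinely differ: nitrite adds no carrying
  capacity for 3H11 (it is toxic to it), yet 3H11's lumped NO step needs a
  biomass yield under scenario B. The shipped file therefore sets 3H11's
  `beta_NO2 = 0` with `yield_NO2 = 0.030`.
- **Electron donor.** Acetate limitation is optional and off by default
  (the growth equations carry no donor term). When enabled, all rates are
  multiplied by `acetate/(acetate + K_don)` and acetate is drawn down at the
  electron balance: 2 e⁻ per N for NO3⁻ → NO2⁻ and NO2⁻ → ½N2O, 2 e⁻ per
  molecule for N2O → N2, against 8 e⁻ per acetate oxidized.

## Default parameters

The shipped file (`denikin/data/default_parameters.yaml`) tags every value
`source: paper` (a printed estimate of this model family:
`K_i(R12) = 13.23 mM`, `K_i(3H11) = 9.11 mM`, `K_s(3H11, N2O) = 0`,
`beta_NO3 = 0.033`, `beta_NO2 = 0.032` OD/mM for R12) or `source: default`.
Defaults were chosen once to satisfy the documented qualitative phenotypes
and are not fitted quantities:

| parameter | value | rationale |
|---|---|---|
| mu_max R12 on NO2⁻ | 0.16 /h | nitrite supports R12's fastest growth |
| K_s R12 NO2⁻ | 0.5 mM | sub-mM affinity typical of nitrite reducers |
| v_max, K_m R12 NO3⁻ conversion | 0.5 mM/(h·OD), 1.0 mM | slow enough that R12 monocultures never accumulate >0.5 mM nitrite |
| mu_max 3H11 on NO3⁻ | 0.25 /h, K_s 0.05 mM | 3H11 is the faster, higher-affinity nitrate reducer |
| mu_max 3H11 on N2O | 0.10 /h | modest dose-independent N2O growth |
| 3H11 lumped NO step | mu_max 0.16 /h, K_s 0.5 mM | mirrors R12's step; weight 2.0 applies only in scenario B |
| 3H11 capacity | beta_NO3 0.030, beta_N2O 0.010 OD/mM | yields slightly below R12's nitrogen-limited slope |

Any user file with the same schema replaces the defaults everywhere.

## Numerics

- Integration: LSODA (stiff-capable, adaptive) with rtol 1e-8 / atol 1e-9;
  output grid 0.1 h; default horizon 200 h (covers ~150 h batch
  experiments). Post-hoc negativity clipping is asserted below 1e-8.
- Dose-independent (`K_s = 0`) kinetics get a 1e-6 mM smoothing floor so the
  rate is continuous as a pool crosses zero; without it the saturation
  factor switches 0↔1 discontinuously and stiff integrators stall at the
  switching surface. For any concentration above 1e-4 mM the factor
  exceeds 0.9999.
- A fixed-step classical Runge–Kutta integrator (`integrate_rk4`) provides
  an independent numerical cross-check; adaptive and fixed-step paths agree
  within 1e-3 relative on the test model.
- Nitrite AUC uses the trapezoid rule on the output grid.
- Nonlinear fits (lmfit least squares) run from 5 log-spaced starts; ties
  and local minima resolve to the lowest chi-square. `K_s`, `K_i`, `V_max`
  bounds keep estimates nonnegative; a fitted `K_i` above 100x the largest
  observed inhibitor level is reported infinite with a `no_inhibition`
  flag, and a Monod `K_s` beyond the observed range is flagged
  `poorly_identified`.

## Growth-rate extraction

Maximum specific growth rates come from per-curve logistic fits
(`X(t) = X_m / (1 + (X_m/X_0 - 1) e^{-mu t})`), not from smoothed
derivatives. Batch curves in this system deviate from a logistic late in
growth — the inhibitor (nitrite) is itself produced or consumed during the
experiment — so a full-curve fit underestimates the rate at the *initial*
conditions, which is the quantity the cross-condition Monod and inhibition
fits consume. `extract_growth_rates` therefore fits the logistic over an
early window (default: points up to 30% of the rise above baseline). The
window default was calibrated on noiseless simulations by requiring the
extracted rate to match the model's initial-rate formula (agreement within
~1% across titration levels); it is a parameter, not a tuned constant.
Sequential fitting (rates first, then Monod/inhibition across conditions)
is the default; `InhibitionModel` with free `mu_max`/`k_s` provides the
joint refit.

## Synthetic data

The generator emulates anoxic batch titrations and co-culture grids:
deterministic model trajectories sampled every 0.5 h over 150 h, with
multiplicative lognormal OD noise (spectrophotometric error scales with
signal; default sd 5%) and additive Gaussian metabolite noise truncated at
zero (default 0.1 mM). Headspace N2O readings convert to liquid mM via
Henry's law (default 24.2 mM/atm at 25 °C, configurable) and to whole-vessel
mM by ideal-gas mass balance at equilibrium. Replicate counts default to 8.
End-point composition records emulate species-resolved composition
estimates by applying OD noise to the final per-species biomasses.

What the generator does *not* emulate: lag phases beyond what initial
biomass absorbs, evaporation or sampling volume loss, pH/temperature drift,
heteroscedastic instrument drift, or biological replicate-to-replicate
parameter variation. Passing recovery tests therefore demonstrate that the
estimators are consistent for this model family under realistic measurement
noise — not that the model is correct for any particular real dataset.

## Degenerate inputs and edge rules

- A species whose initial substrates give zero carrying capacity is held at
  its inoculum (with a warning), not removed.
- Flat growth curves are reported `converged = False` with rate 0 rather
  than raising; titration pipelines drop them.
- In the genus presence matrix, a log10 relative abundance exactly at the
  threshold (default −6) counts as **absent** (strict inequality); missing
  values are absent. The N2O-producer fraction of the census uses the
  incomplete-denitrifier set as denominator; both rules are recorded in the
  output metadata.
- The 10-genome fixture in `denikin/data/synthetic_toy_genomes.tsv` is
  synthetic, constructed so every census fraction has a hand-countable
  value.

## Known limitations

- No explicit NO or NH4⁺ pools, no O2/pH/temperature dependence, no spatial
  structure, no death or maintenance terms.
- With default inoculum (0.01 OD) the logistic capacity binds slightly
  before substrate exhaustion, so a monoculture converting 10 mM nitrate
  stops at ~9.7 mM accumulated nitrite rather than 10; the 1:1
  stoichiometry itself is exact.
- Carrying capacities are computed per species from the initial pools, so
  in co-culture the summed capacities can exceed what the shared nitrogen
  budget supports; the substrate pools then bind first.
- Standard errors are asymptotic least-squares errors; no profile
  likelihoods or Bayesian uncertainty.
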