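# denikin

Kinetic modeling of pathway-partitioned denitrification in a two-member
synthetic community, plus the genomic census that motivates it.

## The problem

Complete denitrification (NO3⁻ → NO2⁻ → NO → N2O → N2) is rarely encoded in
a single genome: most soil and groundwater isolates are *partial*
denitrifiers, so the pathway runs as a relay across community members that
exchange intermediates. Which intermediates are exchanged decides whether
the community emits N2O, a potent greenhouse gas. `denikin` models a
two-member co-culture ("SynCom") of

- **3H11** — a fast NO3⁻ reducer that also reduces NO and N2O but not NO2⁻,
  so nitrite accumulates around it and inhibits its growth, and
- **R12** — a NO2⁻/NO reducer that rescues 3H11 by consuming nitrite, but
  gains no energy from its own NO3⁻ reduction.

The package is for microbial ecologists and systems biologists who want to
fit this model family to batch growth data, compare intermediate-exchange
topologies, and map the conditions (nitrate load x inoculum composition)
under which nitrite toxicity drives N2O accumulation.

## The model

Each growth-coupled reduction step follows Monod kinetics under a logistic
carrying capacity, with non-competitive Hill inhibition by nitrite:

    mu = w * mu_max * S/(S + K_s) * K_i^n/(K_i^n + [NO2]^n) * (1 - X/X_m)

Per-substrate rates are additive (e.g. mu_R12 = mu_NO2 + mu_NO), the
carrying capacity is linear in initial substrates
(X_m = sum_s beta_s * S_s(0)), and the beta coefficients double as biomass
yields so substrate drawdown and maximum OD stay consistent. R12's
NO3⁻ → NO2⁻ step is a Michaelis–Menten conversion with zero growth. NO is
lumped into the NO2⁻ → N2O step; the two shipped exchange topologies are

- **scenario A**: NO2⁻ and N2O are exchanged (all step weights 1);
- **scenario B**: NO2⁻ and NO are exchanged — encoded as energy-weight
  overrides on the lumped step: 2.0 for 3H11, 0.5 for R12.

Nitrogen atoms (NO3 + NO2 + 2 N2O + 2 N2) are conserved exactly by the ODE
right-hand side.

## Worked example

Generate a synthetic R12 nitrite titration with the shipped parameters,
extract per-curve growth rates, and refit the inhibition constant:

```python
from denikin import fitting, synthetic_data

noise = synthetic_data.NoiseSpec(od_sd=0.01, conc_sd_mM=0.0, seed=101)
growth, metab, truth = synthetic_data.generate_monoculture_titration(
    "R12", "NO2", [1, 2, 4, 6, 8, 10, 14, 20], reps=8, noise=noise
)
rates = fitting.extract_growth_rates(growth, "no2_mM")
ok = rates[rates.converged]
res = fitting.fit_inhibition(
    ok["no2_mM"], ok["mu_max"],
    base={"mu_max": 0.16, "K_s": 0.5}, substrate="inhibitor",
)
print(f"K_i = {res.estimate('K_i'):.2f} mM")
```

This prints `K_i = 13.39 mM`: the nitrite concentration that halves R12's
growth rate, recovered within ~1% of the generating value (13.23 mM) from
64 noisy growth curves. Simulating the co-culture shows the hallmark
phenotype — a transient nitrite pulse that returns below detection:

```python
from denikin import scenarios, simulation

tc = simulation.integrate(
    scenarios.build("syncom_B"), scenarios.initial_state("syncom_B"), t_end=200
)
m = simulation.nitrite_metrics(tc)
print(f"NO2 max = {m['no2_max']:.2f} mM, final = {tc.S['NO2'][-1]:.4f} mM")
# NO2 max = 1.14 mM, final = 0.0088 mM
```

A command-line interface mirrors the library
(`denikin simulate|sweep|fit|scenarios|generate|census ...`).

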