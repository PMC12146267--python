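# Default kinetic parameters for the R12 / 3H11 denitrifying co-culture.
#
# Every value carries a `source` tag:
#   paper   - printed in the study whose model family this package implements
#   default - repository default chosen to satisfy the documented qualitative
#             behavior of the cultures (see docs/methods.md); replace freely
#             with user-supplied estimates.
#
# Units: mu_max 1/h; K_s, K_i, K_m in mM; capacity coefficients in OD600 per
# mM initial substrate; v_max in mM / (h * OD600).
species:
  R12:
    kinetics:
      NO2:
        mu_max: {value: 0.16, source: default}
        K_s: {value: 0.5, source: default}
        K_i: {value: 13.23, source: paper}
        hill_n: {value: 1.0, source: default}
    capacity:
      NO3: {value: 0.033, source: paper}
      NO2: {value: 0.032, source: paper}
    conversions:
      - substrate: NO3
        v_max: {value: 0.5, source: default}
        K_m: {value: 1.0, source: default}
  "3H11":
    kinetics:
      NO3:
        mu_max: {value: 0.25, source: default}
        K_s: {value: 0.05, source: default}
        K_i: {value: 9.11, source: paper}
        hill_n: {value: 1.0, source: default}
      N2O:
        mu_max: {value: 0.10, source: default}
        K_s: {value: 0.0, source: paper}
        K_i: {value: 9.11, source: paper}
        hill_n: {value: 1.0, source: default}
      # Lumped NO-reduction step: only active when the exchange topology
      # routes NO from R12 to 3H11 (scenario B), where its growth
      # contribution is doubled while R12's is halved.
      NO2:
        latent: true
        mu_max: {value: 0.16, source: default}
        K_s: {value: 0.5, source: default}
        K_i: {value: 9.11, source: paper}
        hill_n: {value: 1.0, source: default}
    capacity:
      NO3: {value: 0.030, source: default}
      # nitrite is toxic rather than yield-forming for 3H11: no capacity
      # contribution, but the lumped NO step still needs a biomass yield
      NO2: {value: 0.0, source: default}
      N2O: {value: 0.010, source: default}
    yields:
      NO2: {value: 0.030, source: default}
initial_conditions:
  mono_R12: {NO3: 10.0, NO2: 0.0, N2O: 0.0, inoculum_od: 0.01}
  mono_3H11: {NO3: 10.0, NO2: 0.0, N2O: 0.0, inoculum_od: 0.01}
  syncom_A: {NO3: 10.0, NO2: 0.0, N2O: 0.0, inoculum_od: 0.01, frac_3h11: 0.5}
  syncom_B: {NO3: 10.0, NO2: 0.0, N2O: 0.0, inoculum_od: 0.01, frac_3h11: 0.5}
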