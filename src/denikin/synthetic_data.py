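"""Synthetic experiment generation for every input the pipeline consumes.

Emulates the study conditions of a batch denitrification campaign: anoxic
monoculture titrations over initial substrate (nitrate 1-40 mM, nitrite
0-10 mM, N2O 0-30 mM), co-culture time courses across inoculum-ratio x
nitrate grids, and headspace N2O readings converted to liquid concentration
by Henry's law.  Observations are the deterministic model trajectory plus
configurable measurement noise:

- OD600: multiplicative lognormal (spectrophotometric error scales with
  signal), default sd 5%,
- ion-chromatography metabolites: additive Gaussian truncated at zero,
  default sd 0.1 mM,
- headspace N2O: additive Gaussian on the ppm reading.

A fixed seed makes every dataset byte-reproducible, and the generating
("ground-truth") parameters are always returned alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from denikin import scenarios as _scenarios
from denikin.model_core import CommunityState, model_to_dict
from denikin.simulation import TimeCourse, integrate

#: ideal-gas constant, L*atm/(mol*K)
R_GAS = 0.0820573
#: default sampling cadence (h) of the automated OD reader
DEFAULT_CADENCE = 0.5
#: default batch-experiment duration (h)
DEFAULT_T_END = 150.0


@dataclass
class NoiseSpec:
    """Measurement-noise magnitudes and the RNG seed."""

    od_sd: float = 0.05
    conc_sd_mM: float = 0.1
    n2o_ppm_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.od_sd, self.conc_sd_mM, self.n2o_ppm_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class VesselSpec:
    """Geometry and gas-equilibrium constants of a sealed culture vessel."""

    v_liquid_ml: float = 10.0
    v_headspace_ml: float = 17.0
    temperature_c: float = 25.0
    henry_mM_per_atm: float = 24.2
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if self.v_liquid_ml <= 0 or self.v_headspace_ml <= 0:
            raise ValueError("vessel volumes must be positive")
        if self.henry_mM_per_atm <= 0 or self.pressure_atm <= 0:
            raise ValueError("Henry constant and pressure must be positive")


def headspace_to_liquid_n2o(ppm: float, vessel: VesselSpec) -> dict[str, float]:
    """Convert a headspace N2O reading (ppm) to liquid and whole-vessel mM.

    Henry's law gives the liquid concentration from the partial pressure
    ``p = ppm * 1e-6 * P_total``; the whole-vessel concentration adds the
    ideal-gas moles in the headspace by mass balance (equilibrium assumed)
    and is reported per liquid volume.
    """
    if ppm < 0:
        raise ValueError("ppm must be >= 0")
    p = ppm * 1e-6 * vessel.pressure_atm
    liquid_mM = vessel.henry_mM_per_atm * p
    t_kelvin = vessel.temperature_c + 273.15
    gas_mmol = p * (vessel.v_headspace_ml / 1000.0) / (R_GAS * t_kelvin) * 1000.0
    v_liq_l = vessel.v_liquid_ml / 1000.0
    total_mM = (liquid_mM * v_liq_l + gas_mmol) / v_liq_l
    return {"liquid_mM": liquid_mM, "total_mM": total_mM}


def liquid_to_headspace_n2o(liquid_mM: float, vessel: VesselSpec) -> float:
    """Headspace reading (ppm) in equilibrium with a liquid concentration."""
    if liquid_mM < 0:
        raise ValueError("concentration must be >= 0")
    p = liquid_mM / vessel.henry_mM_per_atm
    return p / vessel.pressure_atm * 1e6


def total_vessel_n2o(liquid_mM: float, vessel: VesselSpec) -> float:
    """Whole-vessel N2O (mM per liquid volume) in equilibrium with the liquid."""
    ppm = liquid_to_headspace_n2o(liquid_mM, vessel)
    return headspace_to_liquid_n2o(ppm, vessel)["total_mM"]


_SPECIES_SCENARIO = {"R12": "mono_R12", "3H11": "mono_3H11"}
_COND_COLS = {"NO3": "no3_mM", "NO2": "no2_mM", "N2O": "n2o_mM"}


def _observe(
    tc: TimeCourse,
    species_label: str,
    cond: dict[str, float],
    frac_3h11: float,
    reps: int,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> tuple[list[dict], list[dict]]:
    growth_rows, metab_rows = [], []
    od = tc.total_od
    meta = {
        "species": species_label,
        "no3_mM": cond.get("NO3", 0.0),
        "no2_mM": cond.get("NO2", 0.0),
        "n2o_mM": cond.get("N2O", 0.0),
        "frac_3h11": frac_3h11,
    }
    for rep in range(1, reps + 1):
        if noise.od_sd > 0:
            od_obs = od * np.exp(rng.normal(0.0, noise.od_sd, size=od.size))
        else:
            od_obs = od.copy()
        for ti, oi in zip(tc.t, od_obs):
            growth_rows.append({"time_h": ti, "od600": oi, "replicate": rep, **meta})
        for pool in ("NO3", "NO2", "N2O"):
            series = tc.S[pool]
            if noise.conc_sd_mM > 0:
                obs = np.maximum(series + rng.normal(0.0, noise.conc_sd_mM, size=series.size), 0.0)
            else:
                obs = series.copy()
            for ti, vi in zip(tc.t, obs):
                metab_rows.append(
                    {"time_h": ti, "replicate": rep, "variable": pool, "value_mM": vi, **meta}
                )
    return growth_rows, metab_rows


def generate_monoculture_titration(
    species: str,
    substrate: str,
    levels,
    reps: int = 8,
    noise: NoiseSpec | None = None,
    params: dict | None = None,
    base_conditions: dict[str, float] | None = None,
    inoculum_od: float = 0.01,
    t_end: float = DEFAULT_T_END,
    cadence: float = DEFAULT_CADENCE,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Monoculture growth + metabolite tables across a substrate titration.

    For each level the monoculture model is simulated once and ``reps``
    noisy observation sets are drawn.  ``base_conditions`` holds substrates
    present at a fixed concentration in every vessel (e.g. 10 mM nitrate
    while nitrite is titrated).  Returns (growth table, metabolite table,
    ground truth).
    """
    if species not in _SPECIES_SCENARIO:
        raise ValueError(f"unknown species {species!r}; expected one of {list(_SPECIES_SCENARIO)}")
    if substrate not in _COND_COLS:
        raise ValueError(f"unknown substrate {substrate!r}")
    levels = [float(v) for v in levels]
    if any(v < 0 for v in levels):
        raise ValueError("titration levels must be >= 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    noise = noise or NoiseSpec()
    rng = noise.rng()
    if params is None:
        params = _scenarios.default_parameters()
    scenario_id = _SPECIES_SCENARIO[species]
    model = _scenarios.build(scenario_id, params=params)
    frac = 1.0 if species == "3H11" else 0.0

    growth_rows: list[dict] = []
    metab_rows: list[dict] = []
    for level in levels:
        cond = dict(base_conditions or {})
        cond[substrate] = level
        state = CommunityState(X={species: inoculum_od}, S={k: float(v) for k, v in cond.items()})
        tc = integrate(model, state, t_end=t_end, t_step=cadence)
        g, m = _observe(tc, species, cond, frac, reps, noise, rng)
        growth_rows.extend(g)
        metab_rows.extend(m)
    truth = {
        "kind": "monoculture_titration",
        "species": species,
        "substrate": substrate,
        "levels": levels,
        "reps": reps,
        "inoculum_od": inoculum_od,
        "base_conditions": dict(base_conditions or {}),
        "noise": {"od_sd": noise.od_sd, "conc_sd_mM": noise.conc_sd_mM, "seed": noise.seed},
        "model": model_to_dict(model),
        "t_end": t_end,
        "cadence": cadence,
    }
    return pd.DataFrame(growth_rows), pd.DataFrame(metab_rows), truth


def generate_syncom_grid(
    no3_levels,
    frac3h11_levels,
    reps: int = 8,
    noise: NoiseSpec | None = None,
    scenario: str = "syncom_B",
    params: dict | None = None,
    total_inoculum: float = 0.01,
    t_end: float = DEFAULT_T_END,
    cadence: float = DEFAULT_CADENCE,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Co-culture time courses over an initial-nitrate x inoculum-ratio grid.

    Also emits end-point species-fraction records (emulating composition
    estimates from species-resolved proteomics).  Returns (growth table,
    metabolite table, composition table, ground truth).
    """
    no3_levels = [float(v) for v in no3_levels]
    frac_levels = [float(v) for v in frac3h11_levels]
    if not no3_levels or not frac_levels:
        raise ValueError("grids must be nonempty")
    if any(not (0 < f < 1) for f in frac_levels):
        raise ValueError("inoculum fractions must lie strictly in (0, 1)")
    noise = noise or NoiseSpec()
    rng = noise.rng()
    if params is None:
        params = _scenarios.default_parameters()
    model = _scenarios.build(scenario, params=params)

    growth_rows: list[dict] = []
    metab_rows: list[dict] = []
    comp_rows: list[dict] = []
    for no3 in no3_levels:
        for frac in frac_levels:
            state = _scenarios.initial_state(
                scenario, params=params, NO3=no3, NO2=0.0, N2O=0.0,
                inoculum_od=total_inoculum, frac_3h11=frac,
            )
            tc = integrate(model, state, t_end=t_end, t_step=cadence)
            cond = {"NO3": no3, "NO2": 0.0, "N2O": 0.0}
            g, m = _observe(tc, "SynCom", cond, frac, reps, noise, rng)
            growth_rows.extend(g)
            metab_rows.extend(m)
            finals = {name: arr[-1] for name, arr in tc.X.items()}
            for rep in range(1, reps + 1):
                noisy = {
                    name: x * math.exp(rng.normal(0.0, noise.od_sd)) if noise.od_sd > 0 else x
                    for name, x in finals.items()
                }
                total = sum(noisy.values())
                comp_rows.append(
                    {
                        "no3_mM": no3,
                        "frac_3h11_inoculum": frac,
                        "replicate": rep,
                        "frac_3h11_final": noisy.get("3H11", 0.0) / total,
                        "frac_R12_final": noisy.get("R12", 0.0) / total,
                    }
                )
    truth = {
        "kind": "syncom_grid",
        "scenario": scenario,
        "no3_levels": no3_levels,
        "frac3h11_levels": frac_levels,
        "reps": reps,
        "total_inoculum": total_inoculum,
        "noise": {"od_sd": noise.od_sd, "conc_sd_mM": noise.conc_sd_mM, "seed": noise.seed},
        "model": model_to_dict(model),
        "t_end": t_end,
        "cadence": cadence,
    }
    return (
        pd.DataFrame(growth_rows),
        pd.DataFrame(metab_rows),
        pd.DataFrame(comp_rows),
        truth,
    )


def generate_rate_dose_response(
    species: str,
    substrate: str,
    levels,
    reps: int = 8,
    rel_sd: float = 0.02,
    seed: int = 0,
    params: dict | None = None,
    inhibitor_mM: float = 0.0,
) -> pd.DataFrame:
    """Direct (substrate, growth rate) dose-response points with relative noise.

    Evaluates the species' specific growth rate at low biomass for each
    substrate level and draws ``reps`` multiplicative-noise observations;
    the reduced form of a titration in which per-curve rates have already
    been extracted.
    """
    from denikin.model_core import growth_rate as _growth_rate

    if params is None:
        params = _scenarios.default_parameters()
    model = _scenarios.build(_SPECIES_SCENARIO[species], params=params)
    sp = model.species[0]
    if substrate not in sp.kinetics:
        raise ValueError(f"{species} has no growth step on {substrate}")
    sk = sp.kinetics[substrate]
    rng = np.random.default_rng(seed)
    rows = []
    for level in [float(v) for v in levels]:
        no2 = level if substrate == "NO2" else inhibitor_mM
        mu = _growth_rate(sk, level, no2, X=0.0, X_m=1.0)
        for rep in range(1, reps + 1):
            obs = mu * math.exp(rng.normal(0.0, rel_sd)) if rel_sd > 0 else mu
            rows.append(
                {"species": species, "substrate": substrate, "level_mM": level,
                 "replicate": rep, "mu": obs}
            )
    return pd.DataFrame(rows)
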