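"""Factories for the concrete mono- and co-culture models.

Four scenarios are shipped:

``mono_R12``
    Nitrite/NO reducer alone: growth on the lumped NO2- -> N2O step plus a
    non-energy-conserving NO3- -> NO2- conversion.
``mono_3H11``
    Fast nitrate and N2O reducer alone: growth on NO3- -> NO2- and
    N2O -> N2; no nitrite reduction, so nitrite accumulates.
``syncom_A``
    Co-culture exchanging NO2- and N2O; all step weights 1.
``syncom_B``
    Co-culture exchanging NO2- and NO.  With NO lumped into the
    NO2- -> N2O step, this is encoded as energy-weight overrides on that
    step: 2.0 for 3H11 (which imports NO) and 0.5 for R12 (which exports
    it), and activates 3H11's otherwise latent lumped step.

Parameter values come from a shipped YAML file in which every entry is
annotated ``source: paper`` (printed in the study) or ``source: default``
(gap-filling repository default); a user file with the same schema can be
substituted anywhere.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

from denikin.model_core import (
    CommunityModel,
    CommunityState,
    ExchangeTopology,
    ModelConfigurationError,
    NonGrowthConversion,
    SpeciesModel,
    SubstrateKinetics,
)

#: species labels used throughout
FAST_SPECIES = "3H11"  # fast NO3-/NO/N2O reducer
SLOW_SPECIES = "R12"  # NO2-/NO reducer

SCENARIO_IDS = ("mono_R12", "mono_3H11", "syncom_A", "syncom_B")

#: scenario-B energy-weight overrides on the lumped NO2- -> N2O step
SCENARIO_B_WEIGHTS = {(FAST_SPECIES, "NO2"): 2.0, (SLOW_SPECIES, "NO2"): 0.5}


@dataclass
class ScenarioSpec:
    """A scenario id plus parameter file and initial-condition template."""

    id: str
    parameters: dict | None = None
    initial: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.id not in SCENARIO_IDS:
            raise ModelConfigurationError(f"unknown scenario id {self.id!r}")


def default_parameters() -> dict:
    """The shipped parameter file as a dict (with ``source`` annotations)."""
    ref = resources.files("denikin.data").joinpath("default_parameters.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def load_parameters(path) -> dict:
    """Load a user parameter file with the same schema as the shipped one."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def _value(entry) -> float:
    """Accept both annotated ``{value: x, source: s}`` and bare numbers."""
    if isinstance(entry, Mapping):
        return float(entry["value"])
    return float(entry)


def _build_species(name: str, block: Mapping, include_latent: bool) -> SpeciesModel:
    kinetics = {}
    for sub, kd in (block.get("kinetics") or {}).items():
        if kd.get("latent", False) and not include_latent:
            continue
        ki = kd.get("K_i")
        ki_val = math.inf if ki is None else _value(ki)
        kinetics[sub] = SubstrateKinetics(
            substrate=sub,
            mu_max=_value(kd["mu_max"]),
            K_s=_value(kd["K_s"]),
            K_i=ki_val,
            hill_n=_value(kd.get("hill_n", 1.0)),
        )
    capacity = {sub: _value(v) for sub, v in (block.get("capacity") or {}).items()}
    yields = {sub: _value(v) for sub, v in (block.get("yields") or {}).items()}
    conversions = [
        NonGrowthConversion(c["substrate"], _value(c["v_max"]), _value(c["K_m"]))
        for c in block.get("conversions", [])
    ]
    return SpeciesModel(
        name=name,
        kinetics=kinetics,
        capacity_coeffs=capacity,
        non_growth_conversions=conversions,
        yields=yields,
    )


def build(spec: ScenarioSpec | str, params: dict | None = None) -> CommunityModel:
    """Construct the CommunityModel for a scenario.

    ``spec`` may be a :class:`ScenarioSpec` or a bare scenario id.  ``params``
    defaults to the shipped parameter file.
    """
    if isinstance(spec, str):
        spec = ScenarioSpec(id=spec)
    if params is None:
        params = spec.parameters or default_parameters()
    species_blocks = params.get("species")
    if not species_blocks:
        raise ModelConfigurationError("parameter file has no species section")

    def need(name: str) -> Mapping:
        if name not in species_blocks:
            raise ModelConfigurationError(f"parameter file is missing species block {name!r}")
        return species_blocks[name]

    if spec.id == "mono_R12":
        sp = _build_species(SLOW_SPECIES, need(SLOW_SPECIES), include_latent=False)
        return CommunityModel(species=[sp], topology=ExchangeTopology(scenario="A"))
    if spec.id == "mono_3H11":
        sp = _build_species(FAST_SPECIES, need(FAST_SPECIES), include_latent=False)
        return CommunityModel(species=[sp], topology=ExchangeTopology(scenario="A"))
    include_latent = spec.id == "syncom_B"
    fast = _build_species(FAST_SPECIES, need(FAST_SPECIES), include_latent=include_latent)
    slow = _build_species(SLOW_SPECIES, need(SLOW_SPECIES), include_latent=include_latent)
    if spec.id == "syncom_A":
        topo = ExchangeTopology(scenario="A")
    else:
        topo = ExchangeTopology(scenario="B", weights=dict(SCENARIO_B_WEIGHTS))
    return CommunityModel(species=[fast, slow], topology=topo)


def initial_state(
    scenario_id: str,
    params: dict | None = None,
    **overrides,
) -> CommunityState:
    """Initial CommunityState from the scenario's shipped template.

    Overrides accept the template keys (``NO3``, ``NO2``, ``N2O``,
    ``inoculum_od``, ``frac_3h11``).
    """
    if params is None:
        params = default_parameters()
    template = copy.deepcopy(
        (params.get("initial_conditions") or {}).get(scenario_id, {})
    )
    template.update(overrides)
    od = float(template.pop("inoculum_od", 0.01))
    frac = float(template.pop("frac_3h11", 0.5))
    S = {k: float(v) for k, v in template.items()}
    if scenario_id == "mono_R12":
        X = {SLOW_SPECIES: od}
    elif scenario_id == "mono_3H11":
        X = {FAST_SPECIES: od}
    else:
        X = {FAST_SPECIES: od * frac, SLOW_SPECIES: od * (1 - frac)}
    return CommunityState(X=X, S=S)


def list_scenarios() -> list[str]:
    return list(SCENARIO_IDS)
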