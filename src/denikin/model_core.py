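"""Growth law, stoichiometry and ODE right-hand side for denitrifying cultures.

The growth model couples Monod substrate saturation to a logistic carrying
capacity, with optional non-competitive Hill inhibition by nitrite:

    mu = energy_weight * mu_max * S/(S + K_s)
         * K_i^n / (K_i^n + NO2^n) * (1 - X/X_m)

Per-substrate rates are additive across a species' growth-coupled reduction
steps.  Nitric oxide is never an explicit pool: the NO2- -> NO -> N2O chain
is lumped into a single NO2- -> N2O step, and the alternative exchange
topology in which NO itself is traded between species is expressed through
``energy_weight`` overrides on that lumped step.

Units: biomass in OD600, time in hours, concentrations in mM.  Nitrogen is
tracked per N atom for NO3- and NO2- and per molecule for N2O and N2 (both
2-N species), so N-atom conservation reads
``NO3 + NO2 + 2*N2O + 2*N2 = const``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

#: substrates that can be growth-coupled
GROWTH_SUBSTRATES = ("NO3", "NO2", "N2O")
#: all shared metabolite pools
POOLS = ("NO3", "NO2", "N2O", "N2", "acetate")
#: reduction products of each lumped step, as (product, mM product per mM substrate)
STEP_PRODUCTS = {"NO3": ("NO2", 1.0), "NO2": ("N2O", 0.5), "N2O": ("N2", 1.0)}
#: N atoms per molecule of each pool
N_ATOMS = {"NO3": 1.0, "NO2": 1.0, "N2O": 2.0, "N2": 2.0, "acetate": 0.0}
#: electrons accepted per mM substrate consumed (per N for NO3/NO2; per molecule N2O)
ELECTRONS_PER_STEP = {"NO3": 2.0, "NO2": 2.0, "N2O": 2.0}
#: electrons donated per mM acetate oxidized to CO2
ELECTRONS_PER_ACETATE = 8.0
#: smoothing floor (mM) applied to K_s = 0 (dose-independent) kinetics
KS_FLOOR = 1e-6


class ModelConfigurationError(ValueError):
    """Raised when a model specification is internally inconsistent."""


class DomainError(ValueError):
    """Raised when a kinetic function receives out-of-domain (negative) input."""


@dataclass
class SubstrateKinetics:
    """Monod-logistic kinetics of one growth-coupled reduction step.

    Parameters
    ----------
    substrate : {"NO3", "NO2", "N2O"}
        Electron acceptor of the lumped step.
    mu_max : float
        Maximum specific growth rate on this substrate (1/h).
    K_s : float
        Half-saturation constant (mM).  ``K_s == 0`` means the rate is
        dose-independent: saturation factor 1 whenever substrate is present.
    K_i : float
        Nitrite inhibition constant (mM); ``inf`` disables inhibition.
    hill_n : float
        Steepness of the inhibition term (>= 1).
    energy_weight : float
        Multiplier on the step's growth contribution; used to re-weight the
        lumped NO2- -> N2O step under alternative exchange topologies.
    """

    substrate: str
    mu_max: float
    K_s: float
    K_i: float = math.inf
    hill_n: float = 1.0
    energy_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.substrate not in GROWTH_SUBSTRATES:
            raise ModelConfigurationError(f"unknown growth substrate {self.substrate!r}")
        if self.mu_max < 0 or self.K_s < 0:
            raise ModelConfigurationError("mu_max and K_s must be nonnegative")
        if not (self.K_i > 0):
            raise ModelConfigurationError("K_i must be positive (or infinite)")
        if self.hill_n < 1:
            raise ModelConfigurationError("hill_n must be >= 1")
        if self.energy_weight < 0:
            raise ModelConfigurationError("energy_weight must be nonnegative")


@dataclass
class NonGrowthConversion:
    """A reduction step that carries flux but yields no growth.

    Michaelis-Menten rate ``v_max * S/(S + K_m) * X`` (mM/h), e.g. R12's
    nitrate-to-nitrite conversion, which conserves no energy for growth.
    """

    substrate: str
    v_max: float
    K_m: float

    def __post_init__(self) -> None:
        if self.substrate not in STEP_PRODUCTS:
            raise ModelConfigurationError(f"unknown conversion substrate {self.substrate!r}")
        if self.v_max < 0 or self.K_m < 0:
            raise ModelConfigurationError("v_max and K_m must be nonnegative")


@dataclass
class SpeciesModel:
    """Kinetic parameter bundle for one species.

    ``capacity_coeffs`` maps substrates to the linear carrying-capacity
    coefficients beta (OD600 per mM of initial substrate); the same beta
    serves as the biomass yield of the corresponding growth step, keeping
    maximum-OD predictions and substrate drawdown mutually consistent.
    """

    name: str
    kinetics: dict[str, SubstrateKinetics] = field(default_factory=dict)
    capacity_coeffs: dict[str, float] = field(default_factory=dict)
    non_growth_conversions: list[NonGrowthConversion] = field(default_factory=list)
    X_m_fixed: float | None = None
    yields: dict[str, float] = field(default_factory=dict)

    def yield_for(self, substrate: str) -> float:
        """Biomass yield (OD per mM) of a growth step; defaults to beta."""
        return self.yields.get(substrate, self.capacity_coeffs.get(substrate, 0.0))

    def __post_init__(self) -> None:
        for sub, sk in self.kinetics.items():
            if sk.substrate != sub:
                raise ModelConfigurationError(
                    f"kinetics key {sub!r} does not match substrate {sk.substrate!r}"
                )
        for beta in self.capacity_coeffs.values():
            if beta < 0:
                raise ModelConfigurationError("capacity coefficients must be >= 0")
        growth_subs = set(self.kinetics)
        conv_subs = {c.substrate for c in self.non_growth_conversions}
        overlap = growth_subs & conv_subs
        if overlap:
            raise ModelConfigurationError(
                f"substrates {sorted(overlap)} appear both as growth-coupled and "
                "non-growth steps"
            )
        for sub in growth_subs:
            if self.yield_for(sub) <= 0:
                raise ModelConfigurationError(
                    f"growth step on {sub} requires a positive yield "
                    f"coefficient for species {self.name!r}"
                )


@dataclass
class ExchangeTopology:
    """Which intermediates are exchanged, and step re-weighting.

    Scenario "A" exchanges NO2- and N2O between species (all weights 1).
    Scenario "B" additionally routes NO from the nitrite reducer to the
    fast reducer; with NO lumped into the NO2- -> N2O step this is encoded
    purely as energy-weight overrides on that step (2x for the NO-importing
    species, 0.5x for the exporter).
    """

    scenario: str = "A"
    lumped_no: bool = True
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B"):
            raise ModelConfigurationError("scenario must be 'A' or 'B'")
        if not self.lumped_no:
            raise ModelConfigurationError("NO is never an explicit pool (lumped_no=True)")
        for w in self.weights.values():
            if w < 0:
                raise ModelConfigurationError("topology weights must be >= 0")


@dataclass
class DonorSettings:
    """Optional electron-donor (acetate) limitation; off by default."""

    initial_acetate: float = 0.0
    K_don: float = 0.1
    electrons_per_step: dict[str, float] = field(
        default_factory=lambda: dict(ELECTRONS_PER_STEP)
    )
    electrons_per_acetate: float = ELECTRONS_PER_ACETATE
    limiting: bool = False


@dataclass
class CommunityModel:
    """A set of species drawing on shared substrate pools."""

    species: list[SpeciesModel]
    topology: ExchangeTopology = field(default_factory=ExchangeTopology)
    donor: DonorSettings | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ModelConfigurationError("a community needs at least one species")
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ModelConfigurationError("species names must be unique")

    def species_by_name(self, name: str) -> SpeciesModel:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)

    def effective_weight(self, species: str, substrate: str) -> float:
        """Energy weight of a step after topology overrides."""
        sp = self.species_by_name(species)
        base = sp.kinetics[substrate].energy_weight
        return self.topology.weights.get((species, substrate), base)


@dataclass
class CommunityState:
    """Biomass and shared metabolite pools at one instant."""

    X: dict[str, float]
    S: dict[str, float]
    t: float = 0.0

    def __post_init__(self) -> None:
        for name, x in self.X.items():
            if x < 0:
                raise DomainError(f"negative biomass for {name!r}")
        for pool in POOLS:
            self.S.setdefault(pool, 0.0)
        for pool, s in self.S.items():
            if s < 0:
                raise DomainError(f"negative concentration for {pool!r}")

    def n_atoms(self) -> float:
        """Total N atoms (mM N) across all nitrogen pools."""
        return sum(N_ATOMS[p] * self.S.get(p, 0.0) for p in POOLS)


def growth_rate(
    sk: SubstrateKinetics, S: float, no2: float, X: float, X_m: float
) -> float:
    """Specific growth rate (1/h) of one step at the given conditions.

    Implements mu = w * mu_max * S/(S+Ks) * Ki^n/(Ki^n + NO2^n) * (1 - X/Xm).
    Biomass above the carrying capacity is clamped to rate 0, as is a
    non-positive capacity (inert species).
    """
    if S < 0 or no2 < 0 or X < 0:
        raise DomainError("substrate, nitrite and biomass must be nonnegative")
    if X_m <= 0 or X >= X_m:
        return 0.0
    if S == 0:
        return 0.0
    # K_s = 0 means dose-independent kinetics; a tiny floor keeps the rate
    # continuous at S -> 0 so stiff integrators do not chatter on the switch
    saturation = S / (S + max(sk.K_s, KS_FLOOR))
    if math.isinf(sk.K_i):
        inhibition = 1.0
    else:
        ratio = (no2 / sk.K_i) ** sk.hill_n
        inhibition = 1.0 / (1.0 + ratio)
    return sk.energy_weight * sk.mu_max * saturation * inhibition * (1.0 - X / X_m)


def carrying_capacity(sp: SpeciesModel, initial_S: Mapping[str, float]) -> float:
    """Carrying capacity X_m (OD600) from initial substrate concentrations.

    Linear model ``X_m = sum_s beta_s * S_s(0)``; a fixed ``X_m_fixed``
    overrides it.  A zero capacity renders the species inert.
    """
    if sp.X_m_fixed is not None:
        return sp.X_m_fixed
    for sub, s0 in initial_S.items():
        if s0 < 0:
            raise DomainError(f"negative initial concentration for {sub!r}")
    return sum(beta * initial_S.get(sub, 0.0) for sub, beta in sp.capacity_coeffs.items())


def total_growth_rate(
    sp: SpeciesModel,
    state: CommunityState,
    X_m: float | None = None,
    weights: Mapping[str, float] | None = None,
    donor_factor: float = 1.0,
) -> float:
    """Total specific growth rate: sum of the species' per-substrate rates.

    ``X_m`` defaults to the capacity computed from the *current* pools; in a
    simulation the capacity fixed at t=0 is passed explicitly.  ``weights``
    optionally overrides per-step energy weights (topology overrides).
    """
    if X_m is None:
        X_m = carrying_capacity(sp, state.S)
    x = state.X.get(sp.name, 0.0)
    no2 = state.S.get("NO2", 0.0)
    mu = 0.0
    for sub, sk in sp.kinetics.items():
        if sub not in state.S:
            raise ModelConfigurationError(f"state has no pool for substrate {sub!r}")
        if weights is not None and sub in weights:
            sk = replace(sk, energy_weight=weights[sub])
        mu += growth_rate(sk, state.S[sub], no2, x, X_m)
    return mu * donor_factor


def community_rhs(
    model: CommunityModel,
    state: CommunityState,
    X_m: Mapping[str, float] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Time derivatives (dX, dS) of biomass and metabolite pools.

    Growth-coupled step ``s`` of species ``i`` consumes substrate at
    ``q = mu_{i,s} X_i / beta_{i,s}`` and produces the next intermediate 1:1
    per N atom (NO3->NO2, NO2-> 1/2 N2O, N2O->N2); non-growth conversions
    carry Michaelis-Menten flux with zero growth.  The returned derivatives
    satisfy N-atom balance exactly.
    """
    for name, x in state.X.items():
        if math.isnan(x):
            raise DomainError(f"NaN biomass for {name!r}")
    dX = {sp.name: 0.0 for sp in model.species}
    dS = {pool: 0.0 for pool in POOLS}

    donor_factor = 1.0
    electrons = 0.0
    donor = model.donor
    if donor is not None and donor.limiting:
        ace = state.S.get("acetate", 0.0)
        donor_factor = ace / (ace + donor.K_don) if ace > 0 else 0.0

    for sp in model.species:
        x = state.X.get(sp.name, 0.0)
        X_m_i = X_m[sp.name] if X_m is not None else carrying_capacity(sp, state.S)
        no2 = state.S.get("NO2", 0.0)
        mu_total = 0.0
        for sub, sk in sp.kinetics.items():
            w = model.effective_weight(sp.name, sub)
            if w != sk.energy_weight:
                sk = replace(sk, energy_weight=w)
            mu_step = donor_factor * growth_rate(sk, state.S[sub], no2, x, X_m_i)
            mu_total += mu_step
            if mu_step > 0 and x > 0:
                q = mu_step * x / sp.yield_for(sub)
                product, stoich = STEP_PRODUCTS[sub]
                dS[sub] -= q
                dS[product] += stoich * q
                if donor is not None and donor.limiting:
                    electrons += donor.electrons_per_step.get(sub, 0.0) * q
        for conv in sp.non_growth_conversions:
            s = state.S.get(conv.substrate, 0.0)
            if s > 0 and x > 0:
                rate = donor_factor * conv.v_max * s / (s + conv.K_m) * x
                product, stoich = STEP_PRODUCTS[conv.substrate]
                dS[conv.substrate] -= rate
                dS[product] += stoich * rate
                if donor is not None and donor.limiting:
                    electrons += donor.electrons_per_step.get(conv.substrate, 0.0) * rate
        dX[sp.name] = mu_total * x

    if donor is not None and donor.limiting and electrons > 0:
        dS["acetate"] -= electrons / donor.electrons_per_acetate

    return dX, dS


# ---------------------------------------------------------------------------
# serialization


def _kinetics_to_dict(sk: SubstrateKinetics) -> dict:
    d = {
        "substrate": sk.substrate,
        "mu_max": sk.mu_max,
        "K_s": sk.K_s,
        "hill_n": sk.hill_n,
        "energy_weight": sk.energy_weight,
    }
    d["K_i"] = "inf" if math.isinf(sk.K_i) else sk.K_i
    return d


def _kinetics_from_dict(d: Mapping) -> SubstrateKinetics:
    ki = d.get("K_i", "inf")
    ki = math.inf if ki in ("inf", None) else float(ki)
    return SubstrateKinetics(
        substrate=d["substrate"],
        mu_max=float(d["mu_max"]),
        K_s=float(d["K_s"]),
        K_i=ki,
        hill_n=float(d.get("hill_n", 1.0)),
        energy_weight=float(d.get("energy_weight", 1.0)),
    )


def model_to_dict(model: CommunityModel) -> dict:
    """Plain-dict representation of a community model (YAML/JSON friendly)."""
    out: dict = {"species": [], "topology": None, "donor": None}
    for sp in model.species:
        out["species"].append(
            {
                "name": sp.name,
                "kinetics": {sub: _kinetics_to_dict(sk) for sub, sk in sp.kinetics.items()},
                "capacity_coeffs": dict(sp.capacity_coeffs),
                "non_growth_conversions": [
                    {"substrate": c.substrate, "v_max": c.v_max, "K_m": c.K_m}
                    for c in sp.non_growth_conversions
                ],
                "X_m_fixed": sp.X_m_fixed,
                "yields": dict(sp.yields),
            }
        )
    topo = model.topology
    out["topology"] = {
        "scenario": topo.scenario,
        "lumped_no": topo.lumped_no,
        "weights": [
            {"species": k[0], "substrate": k[1], "weight": v} for k, v in topo.weights.items()
        ],
    }
    if model.donor is not None:
        d = model.donor
        out["donor"] = {
            "initial_acetate": d.initial_acetate,
            "K_don": d.K_don,
            "electrons_per_step": dict(d.electrons_per_step),
            "electrons_per_acetate": d.electrons_per_acetate,
            "limiting": d.limiting,
        }
    return out


def model_from_dict(d: Mapping) -> CommunityModel:
    """Inverse of :func:`model_to_dict`."""
    species = []
    for spd in d["species"]:
        species.append(
            SpeciesModel(
                name=spd["name"],
                kinetics={
                    sub: _kinetics_from_dict(skd) for sub, skd in spd.get("kinetics", {}).items()
                },
                capacity_coeffs={k: float(v) for k, v in spd.get("capacity_coeffs", {}).items()},
                non_growth_conversions=[
                    NonGrowthConversion(c["substrate"], float(c["v_max"]), float(c["K_m"]))
                    for c in spd.get("non_growth_conversions", [])
                ],
                X_m_fixed=spd.get("X_m_fixed"),
                yields={k: float(v) for k, v in (spd.get("yields") or {}).items()},
            )
        )
    topo_d = d.get("topology") or {}
    topology = ExchangeTopology(
        scenario=topo_d.get("scenario", "A"),
        lumped_no=topo_d.get("lumped_no", True),
        weights={
            (w["species"], w["substrate"]): float(w["weight"])
            for w in topo_d.get("weights", [])
        },
    )
    donor = None
    dd = d.get("donor")
    if dd is not None:
        donor = DonorSettings(
            initial_acetate=float(dd.get("initial_acetate", 0.0)),
            K_don=float(dd.get("K_don", 0.1)),
            electrons_per_step={
                k: float(v) for k, v in dd.get("electrons_per_step", ELECTRONS_PER_STEP).items()
            },
            electrons_per_acetate=float(dd.get("electrons_per_acetate", ELECTRONS_PER_ACETATE)),
            limiting=bool(dd.get("limiting", False)),
        )
    return CommunityModel(species=species, topology=topology, donor=donor)


def save_model(model: CommunityModel, path) -> None:
    """Write a community model to YAML (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> CommunityModel:
    """Read a community model from YAML."""
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
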