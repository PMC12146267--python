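"""ODE integration of community models and trajectory summaries.

Integrates the Monod-logistic community equations with a stiff-capable
adaptive solver (LSODA, atol 1e-9 / rtol 1e-8), checks N-atom conservation,
and provides trajectory summary metrics (nitrite maximum and area under the
curve) plus the nitrate x community-composition grid sweep used to map
conditions that drive nitrite accumulation.

A fixed-step classical Runge-Kutta integrator is included as an independent
numerical cross-check of the adaptive path.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from denikin.model_core import (
    POOLS,
    CommunityModel,
    CommunityState,
    DomainError,
    carrying_capacity,
    community_rhs,
    model_to_dict,
)

#: default output grid spacing (h)
DEFAULT_T_STEP = 0.1
#: default horizon (h); covers the ~150 h batch experiments with margin
DEFAULT_T_END = 200.0
#: tolerated magnitude of post-step negativity clipping
CLIP_TOL = 1e-8


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid state when available."""

    def __init__(self, message: str, last_state: CommunityState | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class TimeCourse:
    """Simulated or observed trajectory of biomass and metabolites."""

    t: np.ndarray
    X: dict[str, np.ndarray]
    S: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be 1-D and strictly increasing")
        n = self.t.size
        for name, arr in {**self.X, **self.S}.items():
            if np.asarray(arr).shape != (n,):
                raise ValueError(f"series {name!r} length does not match time grid")

    @property
    def total_od(self) -> np.ndarray:
        return np.sum(list(self.X.values()), axis=0)

    def species_fractions(self, index: int = -1) -> dict[str, float]:
        """Biomass fractions X_i / sum(X) at one time point (default: final)."""
        total = self.total_od[index]
        if total <= 0:
            raise ValueError("zero total biomass; fractions undefined")
        return {name: float(arr[index] / total) for name, arr in self.X.items()}

    def max_specific_growth_rate(self, species: str | None = None) -> float:
        """Realized maximum of d ln X / dt along the trajectory.

        With ``species=None`` the rate of total community biomass is used,
        which is how a growth curve of a co-culture would be read.
        """
        x = self.X[species] if species is not None else self.total_od
        x = np.maximum(x, 1e-12)
        rate = np.gradient(np.log(x), self.t)
        return float(np.max(rate))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_h, variable, value)."""
        frames = []
        for name, arr in self.X.items():
            frames.append(pd.DataFrame({"time_h": self.t, "variable": f"OD_{name}", "value": arr}))
        for pool, arr in self.S.items():
            frames.append(pd.DataFrame({"time_h": self.t, "variable": pool, "value": arr}))
        return pd.concat(frames, ignore_index=True)


def _pack(state: CommunityState, names: list[str]) -> np.ndarray:
    return np.array([state.X[n] for n in names] + [state.S[p] for p in POOLS], dtype=float)


def _unpack(y: np.ndarray, names: list[str]) -> tuple[dict, dict]:
    X = {n: y[i] for i, n in enumerate(names)}
    S = {p: y[len(names) + j] for j, p in enumerate(POOLS)}
    return X, S


def _rhs_vector(model: CommunityModel, names: list[str], X_m: dict[str, float]):
    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        if np.any(np.isnan(y)):
            raise DomainError(f"NaN state at t={t:.3f}")
        yc = np.maximum(y, 0.0)  # guard tiny solver undershoots
        X, S = _unpack(yc, names)
        state = CommunityState(X=X, S=S, t=t)
        dX, dS = community_rhs(model, state, X_m=X_m)
        return np.array([dX[n] for n in names] + [dS[p] for p in POOLS])

    return rhs


def _capacities(model: CommunityModel, initial: CommunityState) -> dict[str, float]:
    X_m = {}
    for sp in model.species:
        xm = carrying_capacity(sp, initial.S)
        if xm <= 0 and initial.X.get(sp.name, 0.0) > 0 and sp.kinetics:
            warnings.warn(
                f"species {sp.name!r} has zero carrying capacity under these initial "
                "substrates; it is held at its inoculum",
                stacklevel=3,
            )
        X_m[sp.name] = xm
    return X_m


def integrate(
    model: CommunityModel,
    initial: CommunityState,
    t_end: float = DEFAULT_T_END,
    t_step: float = DEFAULT_T_STEP,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> TimeCourse:
    """Integrate the community ODEs and return the trajectory.

    Carrying capacities are fixed from the initial substrate pools.  Small
    negative excursions from the solver are clipped to zero after the fact;
    the clip magnitude is asserted to stay below ``CLIP_TOL``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    names = [sp.name for sp in model.species]
    X_m = _capacities(model, initial)
    y0 = _pack(initial, names)
    t_eval = np.arange(0.0, t_end + 0.5 * t_step, t_step)
    t_eval[-1] = min(t_eval[-1], t_end)
    sol = solve_ivp(
        _rhs_vector(model, names, X_m),
        (0.0, t_end),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = None
        if sol.y.size:
            X, S = _unpack(np.maximum(sol.y[:, -1], 0.0), names)
            last = CommunityState(X=X, S=S, t=float(sol.t[-1]))
        raise IntegrationError(f"integration failed: {sol.message}", last_state=last)
    y = sol.y
    clip = float(np.max(-np.minimum(y, 0.0), initial=0.0))
    if clip >= CLIP_TOL:
        raise IntegrationError(f"negative concentrations beyond tolerance (|min|={clip:.2e})")
    y = np.maximum(y, 0.0)
    X = {n: y[i] for i, n in enumerate(names)}
    S = {p: y[len(names) + j] for j, p in enumerate(POOLS)}
    prov = {
        "model_hash": hashlib.sha256(
            json.dumps(model_to_dict(model), sort_keys=True).encode()
        ).hexdigest()[:16],
        "initial": {"X": dict(initial.X), "S": dict(initial.S)},
        "method": method,
        "rtol": rtol,
        "atol": atol,
    }
    return TimeCourse(t=sol.t, X=X, S=S, provenance=prov)


def integrate_rk4(
    model: CommunityModel,
    initial: CommunityState,
    t_end: float,
    dt: float = 1e-3,
    t_step: float = DEFAULT_T_STEP,
) -> TimeCourse:
    """Fixed-step classical Runge-Kutta integration (numerical cross-check)."""
    names = [sp.name for sp in model.species]
    X_m = _capacities(model, initial)
    rhs = _rhs_vector(model, names, X_m)
    n_out = int(round(t_end / t_step)) + 1
    t_out = np.linspace(0.0, t_end, n_out)
    y = _pack(initial, names)
    ys = [y.copy()]
    t = 0.0
    for k in range(1, n_out):
        target = t_out[k]
        while t < target - 1e-12:
            h = min(dt, target - t)
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        ys.append(np.maximum(y, 0.0).copy())
    arr = np.array(ys).T
    X = {n: arr[i] for i, n in enumerate(names)}
    S = {p: arr[len(names) + j] for j, p in enumerate(POOLS)}
    return TimeCourse(t=t_out, X=X, S=S, provenance={"method": "rk4", "dt": dt})


def nitrite_metrics(tc: TimeCourse) -> dict[str, float]:
    """Nitrite maximum (mM) and trapezoidal AUC (mM*h) of a trajectory."""
    if "NO2" not in tc.S:
        raise ValueError("trajectory has no NO2 series")
    no2 = np.asarray(tc.S["NO2"], dtype=float)
    if no2.size == 0:
        raise ValueError("empty trajectory")
    return {
        "no2_max": float(np.max(no2)),
        "no2_auc": float(np.trapezoid(no2, tc.t)),
    }


@dataclass
class SweepResult:
    """Grid sweep of initial nitrate x inoculum composition."""

    no3_grid: np.ndarray
    frac_grid: np.ndarray
    no2_auc: np.ndarray
    no2_max: np.ndarray
    final_n2o: np.ndarray
    final_od: dict[str, np.ndarray]
    failures: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per (cell, metric)."""
        rows = []
        metrics = {"no2_auc": self.no2_auc, "no2_max": self.no2_max, "final_n2o": self.final_n2o}
        for name, arr in self.final_od.items():
            metrics[f"final_od_{name}"] = arr
        for i, no3 in enumerate(self.no3_grid):
            for j, frac in enumerate(self.frac_grid):
                for metric, arr in metrics.items():
                    rows.append(
                        {"no3_mM": no3, "frac_3h11": frac, "metric": metric, "value": arr[i, j]}
                    )
        return pd.DataFrame(rows)


def sweep_grid(
    model_template: CommunityModel,
    no3_grid,
    frac3h11_grid,
    total_inoculum: float = 0.01,
    fast_species: str = "3H11",
    t_end: float = DEFAULT_T_END,
    t_step: float = DEFAULT_T_STEP,
    **integrate_kwargs,
) -> SweepResult:
    """One simulation per (initial NO3-, inoculum fraction) grid cell.

    ``fast_species`` names the species whose inoculum fraction is varied;
    the remainder of ``total_inoculum`` is assigned to the other species.
    Per-cell integration failures are recorded and the sweep continues.
    """
    no3_grid = np.asarray(list(no3_grid), dtype=float)
    frac_grid = np.asarray(list(frac3h11_grid), dtype=float)
    if no3_grid.size == 0 or frac_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if np.any((frac_grid <= 0) | (frac_grid >= 1)):
        raise ValueError("fractions must lie strictly in (0, 1)")
    names = [sp.name for sp in model_template.species]
    if fast_species not in names:
        raise KeyError(fast_species)
    others = [n for n in names if n != fast_species]
    shape = (no3_grid.size, frac_grid.size)
    no2_auc = np.zeros(shape)
    no2_max = np.zeros(shape)
    final_n2o = np.zeros(shape)
    final_od = {n: np.zeros(shape) for n in names}
    failures = []
    for i, no3 in enumerate(no3_grid):
        for j, frac in enumerate(frac_grid):
            X0 = {fast_species: total_inoculum * frac}
            rest = total_inoculum * (1 - frac)
            for n in others:
                X0[n] = rest / len(others)
            state = CommunityState(X=X0, S={"NO3": float(no3)})
            try:
                tc = integrate(model_template, state, t_end=t_end, t_step=t_step, **integrate_kwargs)
            except (IntegrationError, DomainError) as exc:
                failures.append({"no3_mM": float(no3), "frac_3h11": float(frac), "error": str(exc)})
                no2_auc[i, j] = no2_max[i, j] = final_n2o[i, j] = np.nan
                for n in names:
                    final_od[n][i, j] = np.nan
                continue
            m = nitrite_metrics(tc)
            no2_auc[i, j] = m["no2_auc"]
            no2_max[i, j] = m["no2_max"]
            final_n2o[i, j] = tc.S["N2O"][-1]
            for n in names:
                final_od[n][i, j] = tc.X[n][-1]
    return SweepResult(
        no3_grid=no3_grid,
        frac_grid=frac_grid,
        no2_auc=no2_auc,
        no2_max=no2_max,
        final_n2o=final_n2o,
        final_od=final_od,
        failures=failures,
    )
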