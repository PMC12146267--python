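"""Parameter estimation from growth curves and metabolite time series.

Each fitting stage is an sklearn-style estimator (``fit`` / ``predict``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes) so
stages compose with scikit-learn tooling; the module-level ``fit_*``
functions are thin wrappers returning a :class:`FitResult`.

The two-stage procedure mirrors how batch growth data are usually reduced:
per-curve logistic fits extract the maximum specific growth rate and
carrying capacity, then Monod / inhibition / linear-capacity models are fit
across conditions to those summary statistics.  Nonlinear fits run from
multiple log-spaced starting points to avoid local minima.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.integrate import solve_ivp
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from denikin.model_core import CommunityModel, CommunityState
from denikin.simulation import TimeCourse, integrate

#: K_i above this multiple of the largest observed inhibitor concentration is
#: reported as infinite (no measurable inhibition in the data)
INF_KI_FACTOR = 100.0

#: columns of the growth-curve input table
GROWTH_COLUMNS = [
    "time_h",
    "od600",
    "species",
    "replicate",
    "no3_mM",
    "no2_mM",
    "n2o_mM",
    "frac_3h11",
]


def validate_growth_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a growth-curve table against the expected schema."""
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"growth table is missing columns {missing}")
    return df


@dataclass
class FitResult:
    """Estimates with uncertainties and fit diagnostics."""

    parameters: dict[str, tuple[float, float]]
    r_squared: float
    residuals: np.ndarray
    n_points: int
    converged: bool
    method: str
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.residuals.size != self.n_points:
            raise ValueError("residual count must equal n_points")
        for name, (_, se) in self.parameters.items():
            if np.isfinite(se) and se < 0:
                raise ValueError(f"negative standard error for {name!r}")
        if np.isfinite(self.r_squared) and self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")

    def estimate(self, name: str) -> float:
        return self.parameters[name][0]

    def stderr(self, name: str) -> float:
        return self.parameters[name][1]

    def to_dict(self) -> dict:
        return {
            "parameters": {
                k: {"estimate": v[0], "stderr": v[1]} for k, v in self.parameters.items()
            },
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "converged": self.converged,
            "method": self.method,
            "flags": list(self.flags),
        }


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    sstot = float(np.sum((y - y.mean()) ** 2))
    ssres = float(np.sum(resid**2))
    if sstot == 0:
        return 1.0 if ssres == 0 else -math.inf
    return 1.0 - ssres / sstot


def _stderr(param) -> float:
    return float(param.stderr) if param.stderr is not None else math.nan


def logistic_curve(t, mu_max, x_m, x0):
    """Closed-form logistic growth X(t) = Xm / (1 + (Xm/X0 - 1) exp(-mu t))."""
    t = np.asarray(t, dtype=float)
    return x_m / (1.0 + (x_m / x0 - 1.0) * np.exp(-mu_max * t))


class LogisticGrowthModel(BaseEstimator):
    """Logistic fit of one growth curve; extracts mu_max, X_m and X0.

    Parameters
    ----------
    n_starts : int
        Number of log-spaced growth-rate starting values for the
        multi-start least squares.
    min_fold_change : float
        Curves whose OD dynamic range (max/min) falls below this are
        declared non-sigmoidal (``converged_ = False``).
    od_window : float or None
        If set (e.g. 0.5), fit only points up to this fraction of the
        plateau OD.  Batch curves deviate from a logistic late in growth
        when accumulating products (nitrite) depress the rate, dragging a
        full-curve fit below the initial specific rate; an early window
        recovers the rate at the *initial* substrate and inhibitor
        concentrations, which is what the cross-condition Monod and
        inhibition fits consume.
    """

    def __init__(
        self,
        n_starts: int = 5,
        min_fold_change: float = 1.2,
        od_window: float | None = None,
    ):
        self.n_starts = n_starts
        self.min_fold_change = min_fold_change
        self.od_window = od_window

    def fit(self, t, od):
        t = np.asarray(t, dtype=float)
        od = np.asarray(od, dtype=float)
        if t.size < 5:
            raise ValueError("need at least 5 points for a logistic fit")
        if np.any(od <= 0):
            raise ValueError("OD values must be positive")
        order = np.argsort(t)
        t, od = t[order], od[order]
        if self.od_window is not None:
            threshold = od.min() + self.od_window * (od.max() - od.min())
            keep = od <= threshold
            # keep the window contiguous from the start and large enough to fit
            cut = np.flatnonzero(~keep)
            end = cut[0] if cut.size else od.size
            if end >= 5:
                t, od = t[:end], od[:end]

        model = lmfit.Model(logistic_curve)
        x_m0 = float(od.max())
        x00 = float(min(od[0], x_m0 * 0.99))
        best = None
        for mu0 in np.geomspace(0.01, 1.0, self.n_starts):
            params = model.make_params(
                mu_max=dict(value=mu0, min=0.0),
                x_m=dict(value=x_m0, min=od.max() * 0.5),
                x0=dict(value=max(x00, 1e-8), min=1e-10),
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(od, params, t=t)
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise RuntimeError("logistic fit failed from all starting points")

        self.mu_max_ = float(best.params["mu_max"].value)
        self.x_m_ = float(best.params["x_m"].value)
        self.x0_ = float(best.params["x0"].value)
        flags = []
        converged = bool(best.success)
        if od.max() / od.min() < self.min_fold_change:
            converged = False
            flags.append("non_sigmoidal")
        if self.mu_max_ <= 1e-8:
            converged = False
            flags.append("no_growth")
        resid = od - best.best_fit
        self.result_ = FitResult(
            parameters={
                "mu_max": (self.mu_max_, _stderr(best.params["mu_max"])),
                "X_m": (self.x_m_, _stderr(best.params["x_m"])),
                "X0": (self.x0_, _stderr(best.params["x0"])),
            },
            r_squared=_r_squared(od, resid),
            residuals=resid,
            n_points=t.size,
            converged=converged,
            method="logistic_least_squares",
            flags=flags,
        )
        self.converged_ = converged
        return self

    def predict(self, t):
        return logistic_curve(np.asarray(t, dtype=float), self.mu_max_, self.x_m_, self.x0_)


class MonodModel(BaseEstimator):
    """Monod fit mu(S) = mu_max * S / (S + K_s) across substrate levels."""

    def __init__(self, n_starts: int = 5):
        self.n_starts = n_starts

    def fit(self, S, mu):
        S = np.asarray(S, dtype=float)
        mu = np.asarray(mu, dtype=float)
        if np.unique(S).size < 3:
            raise ValueError("need at least 3 distinct substrate concentrations")

        def monod(s, mu_max, k_s):
            return mu_max * s / (s + k_s)

        model = lmfit.Model(monod)
        smax = float(S.max())
        best = None
        for ks0 in np.geomspace(max(smax * 1e-3, 1e-6), smax * 10, self.n_starts):
            params = model.make_params(
                mu_max=dict(value=max(mu.max(), 1e-6), min=0.0),
                k_s=dict(value=ks0, min=0.0),
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(mu, params, s=S)
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise RuntimeError("Monod fit failed from all starting points")

        self.mu_max_ = float(best.params["mu_max"].value)
        self.k_s_ = float(best.params["k_s"].value)
        flags = []
        se_ks = _stderr(best.params["k_s"])
        if self.k_s_ > smax or (np.isfinite(se_ks) and se_ks > max(self.k_s_, 1e-12)):
            flags.append("poorly_identified")
        resid = mu - best.best_fit
        self.result_ = FitResult(
            parameters={
                "mu_max": (self.mu_max_, _stderr(best.params["mu_max"])),
                "K_s": (self.k_s_, se_ks),
            },
            r_squared=_r_squared(mu, resid),
            residuals=resid,
            n_points=S.size,
            converged=bool(best.success),
            method="monod_least_squares",
            flags=flags,
        )
        self.converged_ = bool(best.success)
        return self

    def predict(self, S):
        S = np.asarray(S, dtype=float)
        return self.mu_max_ * S / (S + self.k_s_)


class InhibitionModel(BaseEstimator):
    """Non-competitive Hill inhibition fit of growth rate versus nitrite.

    Fits mu(I) = mu_max * S/(S+K_s) * 1/(1 + (I/K_i)^n) where the growth
    substrate S is either the inhibitor itself (``substrate="inhibitor"``,
    the case of a nitrite reducer inhibited by its own substrate) or a
    constant concentration of another substrate.

    ``mu_max`` and ``k_s`` are the base Monod parameters (supplied or
    co-fitted when None).  Data showing no rate decline yield an infinite
    ``k_i_`` with a ``no_inhibition`` flag.
    """

    def __init__(
        self,
        mu_max: float | None = None,
        k_s: float | None = None,
        substrate: float | str = "inhibitor",
        fit_hill: bool = False,
        hill_n: float = 1.0,
        n_starts: int = 5,
    ):
        self.mu_max = mu_max
        self.k_s = k_s
        self.substrate = substrate
        self.fit_hill = fit_hill
        self.hill_n = hill_n
        self.n_starts = n_starts

    def _substrate_conc(self, I: np.ndarray) -> np.ndarray:
        if isinstance(self.substrate, str):
            if self.substrate != "inhibitor":
                raise ValueError("substrate must be a concentration or 'inhibitor'")
            return I
        return np.full_like(I, float(self.substrate))

    def fit(self, no2, mu):
        I = np.asarray(no2, dtype=float)
        mu = np.asarray(mu, dtype=float)
        if np.unique(I).size < 4:
            raise ValueError("need >= 4 distinct nitrite levels spanning the inhibitory range")
        S = self._substrate_conc(I)

        def inhibited(i, mu_max, k_s, k_i, n, s):
            sat = np.where(s > 0, s / (s + k_s), 0.0)
            return mu_max * sat / (1.0 + (i / k_i) ** n)

        model = lmfit.Model(inhibited, independent_vars=["i", "s"])
        imax = float(I.max())
        ki_upper = imax * INF_KI_FACTOR * 100
        best = None
        for ki0 in np.geomspace(max(imax * 0.05, 1e-3), imax * 20, self.n_starts):
            params = model.make_params(
                mu_max=dict(
                    value=self.mu_max if self.mu_max is not None else max(mu.max(), 1e-6),
                    vary=self.mu_max is None,
                    min=0.0,
                ),
                k_s=dict(
                    value=self.k_s if self.k_s is not None else imax / 10,
                    vary=self.k_s is None,
                    min=0.0,
                ),
                k_i=dict(value=ki0, min=1e-6, max=ki_upper),
                n=dict(value=self.hill_n, vary=self.fit_hill, min=1.0),
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(mu, params, i=I, s=S)
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise RuntimeError("inhibition fit failed from all starting points")

        ki = float(best.params["k_i"].value)
        flags = []
        if ki > imax * INF_KI_FACTOR:
            ki = math.inf
            flags.append("no_inhibition")
        self.k_i_ = ki
        self.hill_n_ = float(best.params["n"].value)
        self.mu_max_ = float(best.params["mu_max"].value)
        self.k_s_ = float(best.params["k_s"].value)
        resid = mu - best.best_fit
        parameters = {"K_i": (ki, _stderr(best.params["k_i"]))}
        if self.fit_hill:
            parameters["hill_n"] = (self.hill_n_, _stderr(best.params["n"]))
        if self.mu_max is None:
            parameters["mu_max"] = (self.mu_max_, _stderr(best.params["mu_max"]))
        if self.k_s is None:
            parameters["K_s"] = (self.k_s_, _stderr(best.params["k_s"]))
        self.result_ = FitResult(
            parameters=parameters,
            r_squared=_r_squared(mu, resid),
            residuals=resid,
            n_points=I.size,
            converged=bool(best.success),
            method="hill_inhibition_least_squares",
            flags=flags,
        )
        self.converged_ = bool(best.success)
        return self

    def predict(self, no2):
        I = np.asarray(no2, dtype=float)
        S = self._substrate_conc(I)
        sat = np.where(S > 0, S / (S + self.k_s_), 0.0)
        if math.isinf(self.k_i_):
            return self.mu_max_ * sat
        return self.mu_max_ * sat / (1.0 + (I / self.k_i_) ** self.hill_n_)


class CapacityOLS(BaseEstimator):
    """Through-origin OLS of maximum OD600 on initial substrate concentrations.

    No intercept: zero substrate implies zero yield above inoculum, matching
    the linear carrying-capacity model X_m = sum_s beta_s S_s(0).
    """

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            design = X.to_numpy(dtype=float)
        else:
            design = np.asarray(X, dtype=float)
            if design.ndim == 1:
                design = design[:, None]
            names = [f"beta_{j}" for j in range(design.shape[1])]
        y = np.asarray(y, dtype=float)
        n, p = design.shape
        if n < p + 1:
            raise ValueError(f"need at least {p + 1} rows for {p} substrates")
        rank = np.linalg.matrix_rank(design)
        if rank < p:
            dependent = []
            for j in range(p):
                others = np.delete(design, j, axis=1)
                if np.linalg.matrix_rank(others) == rank:
                    dependent.append(names[j])
            raise ValueError(f"design matrix is rank deficient; collinear columns: {dependent}")
        ols = sm.OLS(y, design).fit()
        self.feature_names_ = names
        self.coef_ = np.asarray(ols.params, dtype=float)
        self.bse_ = np.asarray(ols.bse, dtype=float)
        resid = y - design @ self.coef_
        self.result_ = FitResult(
            parameters={
                name: (float(b), float(se) if np.isfinite(se) else math.nan)
                for name, b, se in zip(names, self.coef_, self.bse_)
            },
            r_squared=float(min(ols.rsquared, 1.0)),
            residuals=resid,
            n_points=n,
            converged=True,
            method="ols_through_origin",
        )
        return self

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_


class ConversionModel(BaseEstimator):
    """Michaelis-Menten fit of a non-growth reduction step.

    Fits dS/dt = -V_max * S/(S+K_m) * X(t) to a substrate depletion series,
    with the biomass series X(t) interpolated between observations.
    """

    def __init__(self, n_starts: int = 5):
        self.n_starts = n_starts

    def fit(self, t, S, od):
        t = np.asarray(t, dtype=float)
        S = np.asarray(S, dtype=float)
        od = np.asarray(od, dtype=float)
        if not (t.size == S.size == od.size):
            raise ValueError("time, substrate and biomass series must be co-timed")
        if t.size < 4:
            raise ValueError("need at least 4 points")
        decline = S[0] - S[-1]
        if decline < -1e-9 - 0.02 * max(S[0], 1e-12):
            raise ValueError("substrate series increases; not a depletion curve")
        if decline > 0.05 * S[0] and np.max(od) <= 1e-9:
            raise ValueError("substrate declines with zero biomass: unexplained flux")

        def predict_S(params):
            vmax = params["v_max"].value
            km = params["k_m"].value

            def rhs(tt, y):
                s = max(y[0], 0.0)
                x = np.interp(tt, t, od)
                return [-vmax * s / (s + km) * x]

            sol = solve_ivp(rhs, (t[0], t[-1]), [S[0]], t_eval=t, rtol=1e-8, atol=1e-10)
            if not sol.success:
                return np.full_like(S, np.inf)
            return sol.y[0]

        def residual(params):
            return predict_S(params) - S

        best = None
        for v0 in np.geomspace(0.01, 10.0, self.n_starts):
            params = lmfit.Parameters()
            params.add("v_max", value=v0, min=0.0)
            params.add("k_m", value=max(S[0] / 5, 1e-3), min=1e-6)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = lmfit.minimize(residual, params)
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise RuntimeError("conversion fit failed from all starting points")
        self.v_max_ = float(best.params["v_max"].value)
        self.k_m_ = float(best.params["k_m"].value)
        resid = np.asarray(best.residual, dtype=float)
        self.result_ = FitResult(
            parameters={
                "V_max": (self.v_max_, _stderr(best.params["v_max"])),
                "K_m": (self.k_m_, _stderr(best.params["k_m"])),
            },
            r_squared=_r_squared(S, resid),
            residuals=resid,
            n_points=t.size,
            converged=bool(best.success),
            method="michaelis_menten_depletion",
        )
        return self


@dataclass
class CalibrationResult:
    """Outcome of the initial-biomass (lag-phase) calibration."""

    x0: dict[str, float]
    rmse: float
    rmse_initial: float
    flags: list[str] = field(default_factory=list)


def _trajectory_rmse(
    model: CommunityModel,
    initial: CommunityState,
    data: TimeCourse,
) -> float:
    t_end = float(data.t[-1])
    t_step = max(min(np.min(np.diff(data.t)), 0.5), 0.01)
    sim = integrate(model, initial, t_end=t_end, t_step=t_step)
    sq, n = 0.0, 0
    for name, obs in data.X.items():
        if name in sim.X:
            pred = np.interp(data.t, sim.t, sim.X[name])
            sq += float(np.sum((pred - obs) ** 2))
            n += obs.size
    for pool, obs in data.S.items():
        if pool in sim.S:
            pred = np.interp(data.t, sim.t, sim.S[pool])
            sq += float(np.sum((pred - np.asarray(obs)) ** 2))
            n += np.asarray(obs).size
    if n == 0:
        raise ValueError("no overlapping variables between model and data")
    return math.sqrt(sq / n)


def calibrate_initial_biomass(
    model: CommunityModel,
    observed: TimeCourse,
    inoculum_od: float = 0.01,
    x0_lower: float = 1e-6,
) -> CalibrationResult:
    """Fit per-species initial biomass to the observed trajectory.

    The initial biomass is the free parameter that effectively adjusts lag
    phase; the search is on a log scale, bounded by
    ``[x0_lower, inoculum_od]``.  Initial substrate pools are taken from the
    first observation.
    """
    names = [sp.name for sp in model.species]
    S0 = {pool: float(arr[0]) for pool, arr in observed.S.items()}
    flags: list[str] = []

    obs_series = [arr for arr in observed.X.values()] or [observed.total_od]
    dyn = max(float(np.max(a) / max(np.min(a), 1e-12)) for a in obs_series)
    start = {n: inoculum_od for n in names}
    rmse_initial = _trajectory_rmse(
        model, CommunityState(X=dict(start), S=dict(S0)), observed
    )
    if dyn < 1.2:
        flags.append("flat_observation")
        return CalibrationResult(
            x0={n: x0_lower for n in names},
            rmse=rmse_initial,
            rmse_initial=rmse_initial,
            flags=flags,
        )

    lo, hi = math.log10(x0_lower), math.log10(inoculum_od)

    def objective(logx):
        logx = np.clip(logx, lo, hi)
        X0 = {n: 10.0 ** v for n, v in zip(names, logx)}
        try:
            return _trajectory_rmse(model, CommunityState(X=X0, S=dict(S0)), observed)
        except Exception:
            return 1e6

    x_init = np.array([math.log10(start[n]) for n in names])
    res = minimize(objective, x_init, method="Nelder-Mead", options={"xatol": 1e-3, "fatol": 1e-10})
    logx = np.clip(res.x, lo, hi)
    x0 = {n: float(10.0 ** v) for n, v in zip(names, logx)}
    rmse = objective(res.x)
    if rmse > rmse_initial:
        x0 = dict(start)
        rmse = rmse_initial
        flags.append("calibration_no_improvement")
    for n, v in x0.items():
        if abs(math.log10(v) - lo) < 1e-6:
            flags.append(f"at_lower_bound:{n}")
        if abs(math.log10(v) - hi) < 1e-6:
            flags.append(f"at_upper_bound:{n}")
    return CalibrationResult(x0=x0, rmse=rmse, rmse_initial=rmse_initial, flags=flags)


def compare_scenarios(
    models: Mapping[str, CommunityModel],
    data: TimeCourse,
    initial: CommunityState,
    t_step: float = 0.1,
) -> pd.DataFrame:
    """Score exchange scenarios by RMSE against a shared observed trajectory.

    Each model is simulated from the same initial conditions, interpolated
    linearly onto the data's time grid, and compared on every overlapping
    (time, variable) point.  Rows with ``variable == "total"`` give the
    pooled RMSE per scenario; the lowest total marks the supported scenario.
    """
    rows = []
    for label, model in models.items():
        sim = integrate(model, initial, t_end=float(data.t[-1]), t_step=t_step)
        sq_total, n_total = 0.0, 0
        per_var: dict[str, tuple[float, int]] = {}
        for name, obs in data.X.items():
            if name in sim.X:
                pred = np.interp(data.t, sim.t, sim.X[name])
                per_var[f"OD_{name}"] = (float(np.sum((pred - obs) ** 2)), obs.size)
        for pool, obs in data.S.items():
            if pool in sim.S:
                pred = np.interp(data.t, sim.t, sim.S[pool])
                per_var[pool] = (float(np.sum((np.asarray(obs) - pred) ** 2)), len(obs))
        if not per_var:
            raise ValueError("no overlapping variables between model and data")
        for var, (sq, n) in per_var.items():
            rows.append({"scenario": label, "variable": var, "rmse": math.sqrt(sq / n), "n": n})
            sq_total += sq
            n_total += n
        rows.append(
            {
                "scenario": label,
                "variable": "total",
                "rmse": math.sqrt(sq_total / n_total),
                "n": n_total,
            }
        )
    return pd.DataFrame(rows)


def extract_growth_rates(
    growth_df: pd.DataFrame,
    level_col: str,
    group_cols: Sequence[str] = ("species", "replicate"),
    od_window: float | None = 0.3,
) -> pd.DataFrame:
    """Per-curve logistic fits across a titration table.

    Groups the table by the titrated level plus ``group_cols``, fits a
    logistic to each curve and returns one row per curve with the estimated
    ``mu_max``, ``X_m``, ``X0`` and a convergence flag.  Non-growing (flat)
    curves are reported with ``mu_max = 0`` and ``converged = False``.
    """
    validate_growth_table(growth_df)
    rows = []
    for keys, grp in growth_df.groupby([level_col, *group_cols], sort=True):
        level = keys[0]
        est = LogisticGrowthModel(od_window=od_window)
        try:
            est.fit(grp["time_h"].to_numpy(), grp["od600"].to_numpy())
            mu, xm, x0 = est.mu_max_, est.x_m_, est.x0_
            conv = est.converged_
        except (ValueError, RuntimeError):
            mu, xm, x0, conv = 0.0, float(grp["od600"].max()), float(grp["od600"].iloc[0]), False
        if not conv:
            mu = 0.0
        row = {level_col: level, "mu_max": mu, "X_m": xm, "X0": x0, "converged": conv}
        row.update({c: k for c, k in zip(group_cols, keys[1:])})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_logistic(t, od, **kwargs) -> FitResult:
    """Logistic growth-curve fit; returns mu_max, X_m and X0."""
    return LogisticGrowthModel(**kwargs).fit(t, od).result_


def fit_monod(S, mu, **kwargs) -> FitResult:
    """Monod fit of growth rate versus substrate concentration."""
    return MonodModel(**kwargs).fit(S, mu).result_


def fit_inhibition(no2, mu, base: Mapping[str, float] | None = None, **kwargs) -> FitResult:
    """Inhibition fit of growth rate versus nitrite, given base Monod parameters."""
    if base is not None:
        kwargs.setdefault("mu_max", base.get("mu_max"))
        kwargs.setdefault("k_s", base.get("K_s", base.get("k_s")))
    return InhibitionModel(**kwargs).fit(no2, mu).result_


def fit_capacity_ols(X, y) -> FitResult:
    """Through-origin OLS of maximum OD600 on initial substrate concentrations."""
    return CapacityOLS().fit(X, y).result_


def fit_conversion(t, S, od, **kwargs) -> FitResult:
    """Michaelis-Menten fit of a non-growth substrate conversion step."""
    return ConversionModel(**kwargs).fit(t, S, od).result_
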