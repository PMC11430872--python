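"""Thin-layer drying kinetics: moisture ratio and empirical model fitting.

The moisture ratio MR(t) = (X_t - X_e)/(X_0 - X_e) (dry-basis moistures)
normalises a drying curve to [0, 1].  Six classical thin-layer models are
fitted to MR(t) by nonlinear least squares and ranked by goodness of fit:

========================  =======================================  ==========
name                      MR(t)                                    parameters
========================  =======================================  ==========
newton                    exp(-k t)                                k
page                      exp(-k t^n)                              k, n
henderson_pabis           a exp(-k t)                              a, k
logarithmic               a exp(-k t) + c                          a, k, c
wang_singh                1 + a t + b t^2                          a, b
two_term                  a exp(-k t) + c exp(-k0 t)               a, k, c, k0
========================  =======================================  ==========

Fitting follows the statsmodels Model/Results idiom: build a
:class:`ThinLayerModel` from a :class:`MoistureSeries`, call ``fit()`` and
read estimates and diagnostics off the returned :class:`ThinLayerResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import bisect, least_squares

__all__ = [
    "DryingRun",
    "MoistureSeries",
    "ThinLayerModel",
    "ThinLayerResults",
    "MODEL_FORMULAS",
    "MODEL_PARAMS",
    "moisture_ratio",
    "fit_thin_layer_model",
    "fit_all_models",
    "evaluate_fit",
    "rank_models",
    "drying_time_to_target",
]


@dataclass
class DryingRun:
    """One temperature x replicate drying time/mass series.

    ``equilibrium_moisture_db`` is the dry-basis equilibrium moisture Me;
    thin leaves dry to near bone-dry so it defaults to 0.
    """

    run_id: str
    temperature_C: float
    time_min: np.ndarray
    mass_g: np.ndarray
    bone_dry_mass_g: float
    equilibrium_moisture_db: float = 0.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.mass_g = np.asarray(self.mass_g, dtype=float)
        if self.time_min.shape != self.mass_g.shape:
            raise ValueError("time_min and mass_g must have equal length")
        if self.time_min.size < 2:
            raise ValueError("a drying run needs at least two samples")
        if self.time_min[0] != 0:
            raise ValueError("time series must start at t = 0")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.bone_dry_mass_g <= 0:
            raise ValueError("bone_dry_mass_g must be positive")
        if np.any(self.mass_g < self.bone_dry_mass_g - 1e-12):
            raise ValueError("sample mass cannot fall below the bone-dry mass")


@dataclass
class MoistureSeries:
    """Moisture-ratio curve for one run; mr[0] == 1 by construction."""

    time_min: np.ndarray
    mr: np.ndarray
    temperature_C: float = float("nan")

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.mr = np.asarray(self.mr, dtype=float)
        if self.time_min.shape != self.mr.shape:
            raise ValueError("time and mr must have equal length")


def moisture_ratio(run: DryingRun, clip: bool = False) -> MoistureSeries:
    """Convert a mass series to the dimensionless moisture ratio.

    Dry-basis moisture X_t = (m_t - m_dry)/m_dry, then
    MR_t = (X_t - Me)/(X_0 - Me).  With ``clip`` the series is clipped to
    [0, 1] (noisy data can overshoot slightly).

    Raises
    ------
    ValueError
        If the initial moisture does not exceed Me (ratio undefined).
    """
    x = (run.mass_g - run.bone_dry_mass_g) / run.bone_dry_mass_g
    me = run.equilibrium_moisture_db
    denom = x[0] - me
    if denom <= 0:
        raise ValueError(
            f"run {run.run_id}: initial dry-basis moisture {x[0]:.4g} must exceed Me={me:.4g}"
        )
    mr = (x - me) / denom
    if clip:
        mr = np.clip(mr, 0.0, 1.0)
    return MoistureSeries(run.time_min.copy(), mr, run.temperature_C)


# ---------------------------------------------------------------------------
# model registry

def _newton(t, k):
    return np.exp(-k * t)


def _page(t, k, n):
    return np.exp(-k * np.power(t, n, where=t > 0, out=np.zeros_like(t)))


def _henderson_pabis(t, a, k):
    return a * np.exp(-k * t)


def _logarithmic(t, a, k, c):
    return a * np.exp(-k * t) + c


def _wang_singh(t, a, b):
    return 1.0 + a * t + b * t * t


def _two_term(t, a, k, c, k0):
    return a * np.exp(-k * t) + c * np.exp(-k0 * t)


MODEL_FORMULAS = {
    "newton": _newton,
    "page": _page,
    "henderson_pabis": _henderson_pabis,
    "logarithmic": _logarithmic,
    "wang_singh": _wang_singh,
    "two_term": _two_term,
}

MODEL_PARAMS = {
    "newton": ("k",),
    "page": ("k", "n"),
    "henderson_pabis": ("a", "k"),
    "logarithmic": ("a", "k", "c"),
    "wang_singh": ("a", "b"),
    "two_term": ("a", "k", "c", "k0"),
}

# parameter bounds: rates in (0, 10], Page exponent in (0, 5], amplitudes in [-5, 5]
_EPS = 1e-12
_BOUNDS = {
    "k": (_EPS, 10.0),
    "k0": (_EPS, 10.0),
    "n": (_EPS, 5.0),
    "a": (-5.0, 5.0),
    "b": (-5.0, 5.0),
    "c": (-5.0, 5.0),
}


def _newton_log_slope(series: MoistureSeries) -> float:
    """Initial rate guess from a log-linearisation of the Newton model.

    MR values <= 0 (noise) are excluded from the log fit but kept in the SSE.
    """
    mask = series.mr > 0
    t, mr = series.time_min[mask], series.mr[mask]
    if t.size < 2 or np.ptp(t) == 0:
        return 0.01
    slope = np.polyfit(t, np.log(mr), 1)[0]
    return float(np.clip(-slope, 1e-4, 5.0))


def _starts(model_name: str, series: MoistureSeries, rng: np.random.Generator):
    """Multi-start initial guesses; first start is the log-linearised one."""
    k0 = _newton_log_slope(series)
    base = {"k": k0, "n": 1.0, "a": 1.0, "b": 0.0, "c": 0.0, "k0": k0 * 0.5}
    if model_name == "wang_singh":
        base["a"] = -k0
        base["b"] = k0 * k0 / 4
    if model_name == "two_term":
        base["a"], base["c"] = 0.7, 0.3
    names = MODEL_PARAMS[model_name]
    yield np.array([base[p] for p in names])
    if model_name == "two_term":
        # Henderson-Pabis embedding (c = 0): keeps the nested-model SSE ordering
        yield np.array([1.0, k0, 0.0, min(k0 * 0.5 + _EPS, 10.0)])
    for _ in range(4):
        jitter = []
        for p in names:
            lo, hi = _BOUNDS[p]
            v = base[p] * rng.uniform(0.3, 3.0) if base[p] != 0 else rng.uniform(-0.01, 0.01)
            jitter.append(np.clip(v, lo + 1e-9, hi - 1e-9))
        yield np.array(jitter)


@dataclass
class ThinLayerResults:
    """Fitted thin-layer model: parameter estimates and fit diagnostics."""

    model_name: str
    params: dict[str, float]
    r2: float
    mse: float
    converged: bool
    n_obs: int
    series: MoistureSeries | None = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.params)

    def predict(self, time_min) -> np.ndarray:
        t = np.asarray(time_min, dtype=float)
        return MODEL_FORMULAS[self.model_name](t, *[self.params[p] for p in MODEL_PARAMS[self.model_name]])

    @property
    def sse(self) -> float:
        return self.mse * self.n_obs

    def summary(self) -> str:
        lines = [
            f"Thin-layer model fit: {self.model_name}",
            f"  n_obs = {self.n_obs}, converged = {self.converged}",
            f"  R^2 = {self.r2:.6f}, MSE = {self.mse:.6g}",
            "  parameters:",
        ]
        lines += [f"    {p:3s} = {v:.6g}" for p, v in self.params.items()]
        return "\n".join(lines)


class ThinLayerModel:
    """Nonlinear least-squares fit of one named thin-layer model to MR(t).

    Multi-start trust-region least squares (5 seeded starts, the first from
    a log-linearisation of the Newton model) with box bounds on the
    parameters; SSE-change tolerance 1e-10.
    """

    def __init__(self, series: MoistureSeries, model_name: str):
        if model_name not in MODEL_FORMULAS:
            raise ValueError(f"unknown model {model_name!r}; choose from {sorted(MODEL_FORMULAS)}")
        n_par = len(MODEL_PARAMS[model_name])
        if series.mr.size < max(4, n_par + 2):
            raise ValueError(
                f"{model_name} needs at least {max(4, n_par + 2)} observations, got {series.mr.size}"
            )
        self.series = series
        self.model_name = model_name

    def fit(self, init: dict[str, float] | None = None, seed: int = 0) -> ThinLayerResults:
        names = MODEL_PARAMS[self.model_name]
        func = MODEL_FORMULAS[self.model_name]
        t, y = self.series.time_min, self.series.mr
        lo = np.array([_BOUNDS[p][0] for p in names])
        hi = np.array([_BOUNDS[p][1] for p in names])

        def resid(theta):
            return func(t, *theta) - y

        rng = np.random.default_rng(seed)
        starts = list(_starts(self.model_name, self.series, rng))
        if init is not None:
            starts.insert(0, np.clip(np.array([init[p] for p in names]), lo, hi))

        best, best_sse, converged = None, np.inf, False
        for x0 in starts:
            try:
                sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi),
                                    method="trf", ftol=1e-10, xtol=1e-12, gtol=1e-12)
            except Exception:
                continue
            sse = 2.0 * sol.cost
            if sse < best_sse - 1e-15 or best is None:
                best, best_sse = sol, sse
                converged = bool(sol.success)
        if best is None:
            return ThinLayerResults(self.model_name, dict.fromkeys(names, math.nan),
                                    math.nan, math.nan, False, y.size, self.series)
        params = dict(zip(names, best.x.tolist()))
        metrics = evaluate_fit(y, func(t, *best.x))
        return ThinLayerResults(self.model_name, params, metrics["r2"], metrics["mse"],
                                converged, y.size, self.series)


def fit_thin_layer_model(series: MoistureSeries, model_name: str,
                         init: dict[str, float] | None = None, seed: int = 0) -> ThinLayerResults:
    """Functional wrapper around :class:`ThinLayerModel`."""
    return ThinLayerModel(series, model_name).fit(init=init, seed=seed)


def fit_all_models(series: MoistureSeries, seed: int = 0) -> list[ThinLayerResults]:
    """Fit all six thin-layer models and return them ranked best-first."""
    fits = [fit_thin_layer_model(series, name, seed=seed) for name in MODEL_FORMULAS]
    return rank_models(fits)


def evaluate_fit(mr_exp, mr_pre) -> dict[str, float]:
    """Goodness of fit: MSE = (1/N) sum (pre-exp)^2 and R^2 = 1 - SS_res/SS_tot.

    R^2 is NaN (flagged, not raised) when the observations have zero variance.
    """
    exp = np.asarray(mr_exp, dtype=float)
    pre = np.asarray(mr_pre, dtype=float)
    if exp.shape != pre.shape:
        raise ValueError("observed and predicted series must have equal length")
    if exp.size < 2:
        raise ValueError("need at least two points")
    res = pre - exp
    mse = float(np.mean(res * res))
    ss_tot = float(np.sum((exp - exp.mean()) ** 2))
    r2 = math.nan if ss_tot == 0 else 1.0 - float(np.sum(res * res)) / ss_tot
    return {"r2": r2, "mse": mse}


def rank_models(fits: list[ThinLayerResults]) -> list[ThinLayerResults]:
    """Order fits best-first: descending R^2, ties by ascending MSE then by
    fewer parameters; non-converged fits sort after all converged ones."""
    if not fits:
        raise ValueError("rank_models needs at least one fit")

    def key(f: ThinLayerResults):
        r2 = f.r2 if math.isfinite(f.r2) else -np.inf
        mse = f.mse if math.isfinite(f.mse) else np.inf
        return (not f.converged, -r2, mse, f.n_params)

    return sorted(fits, key=key)


def drying_time_to_target(fit: ThinLayerResults, mr_target: float,
                          t_max: float = 1e6) -> float:
    """Smallest t >= 0 at which the fitted curve reaches ``mr_target``.

    Bracketing + bisection on the fitted curve; the Page/Newton closed form
    t = (-ln MR / k)^(1/n) serves as an internal cross-check in the tests.
    """
    if not fit.converged:
        raise ValueError("refusing to invert a non-converged fit")
    if not 0 < mr_target < 1:
        raise ValueError("mr_target must lie in (0, 1)")
    f = lambda t: float(fit.predict(t)) - mr_target
    if f(0.0) <= 0:
        return 0.0
    # expand the bracket geometrically
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > t_max:
            raise ValueError(f"model {fit.model_name} never reaches MR = {mr_target} before t = {t_max}")
    return float(bisect(f, 0.0, hi, xtol=1e-9))
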