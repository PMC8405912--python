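"""Temperature-dependent tobacco dry-weight growth model.

The relative growth rate follows an Arrhenius law attenuated by a
high-temperature enzyme-inactivation term,

    r(T) = A * T * exp(-k / T) / (1 + exp(S - H / T)),

with ``A`` (day^-1 K^-1) the pre-exponential coefficient, ``k`` (K) the
Arrhenius temperature constant, ``S`` (dimensionless) the inactivation
entropy term and ``H`` (K) the inactivation temperature constant.  Dry
weight compounds in discrete time steps,

    W(t + dt) = W(t) + W(t) * r(T) * dt,

so ``r`` acts as a relative (per-day) growth rate even though it is often
quoted in absolute units in the chamber-study literature; see
``docs/methods.md`` for the unit discussion.

Growth-chamber regimes alternate a high temperature (9 h/day by default)
with a low temperature (15 h/day); the model is driven by the
hour-weighted daily mean of the two.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KELVIN_OFFSET",
    "GrowthModelParams",
    "ChamberDataset",
    "FitResult",
    "PUBLISHED_TOBACCO_PARAMS",
    "weighted_day_temperature",
    "growth_rate",
    "step_dry_weight",
    "simulate_trajectory",
    "rmse",
    "r_squared",
    "predict_chamber",
    "fit_growth_params",
    "read_chamber_csv",
    "write_chamber_csv",
]

KELVIN_OFFSET = 273.15


class InvalidDesignError(ValueError):
    """A chamber design violates a structural constraint (e.g. hour split)."""


@dataclass(frozen=True)
class GrowthModelParams:
    """Parameters of the Arrhenius-with-inactivation growth-rate model.

    Attributes
    ----------
    A : float
        Pre-exponential coefficient, day^-1 K^-1.  Must be >= 0 (zero is
        permitted to express a degenerate no-growth model).
    k : float
        Arrhenius temperature constant, K.  Must be > 0.
    S : float
        Dimensionless inactivation entropy term.
    H : float
        Inactivation temperature constant, K.  Must be > 0.
    """

    A: float
    k: float
    S: float
    H: float

    def __post_init__(self) -> None:
        vals = (self.A, self.k, self.S, self.H)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"growth parameters must be finite, got {vals}")
        if self.A < 0:
            raise ValueError(f"A must be non-negative, got {self.A}")
        if self.k <= 0 or self.H <= 0:
            raise ValueError(f"k and H must be positive, got k={self.k}, H={self.H}")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.k, self.S, self.H], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "GrowthModelParams":
        A, k, S, H = (float(v) for v in x)
        return cls(A=A, k=k, S=S, H=H)


#: Growth-model parameters reported for chamber-grown tobacco (RMSE-minimizing
#: fit to the classic Wann & Raper dry-weight chamber data).  Note that with
#: these values the inactivation term exp(S - H/T) is negligible below ~400 K,
#: so r(T) is monotone increasing over horticultural temperatures; see
#: docs/methods.md.
PUBLISHED_TOBACCO_PARAMS = GrowthModelParams(A=924.67, k=1992.0, S=5.434, H=22780.0)


def weighted_day_temperature(
    high: float, low: float, h_high: float = 9.0, h_low: float = 15.0
) -> float:
    """Hour-weighted daily mean temperature of a two-level chamber regime.

    Parameters are the high and low set-point temperatures (K) and the hours
    per day spent at each; the split must sum to 24 h.
    """
    if not (math.isfinite(high) and math.isfinite(low)):
        raise ValueError("temperatures must be finite")
    if h_high < 0 or h_low < 0 or abs(h_high + h_low - 24.0) > 1e-9:
        raise InvalidDesignError(
            f"hour split must be non-negative and sum to 24, got {h_high} + {h_low}"
        )
    return (h_high * high + h_low * low) / 24.0


def growth_rate(T, params: GrowthModelParams):
    """Relative growth rate r(T) in day^-1.

    Accepts a scalar or array temperature in kelvin; temperatures must be
    strictly positive.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0) or not np.all(np.isfinite(T)):
        raise ValueError("temperature must be positive and finite (kelvin)")
    arrhenius = params.A * T * np.exp(-params.k / T)
    inactivation = 1.0 + np.exp(params.S - params.H / T)
    out = arrhenius / inactivation
    return float(out) if out.ndim == 0 else out


def step_dry_weight(w0: float, T: float, dt: float, params: GrowthModelParams) -> float:
    """One explicit-Euler growth step: W0 + W0 * r(T) * dt (g/plant)."""
    if w0 <= 0:
        raise ValueError(f"dry weight must be positive, got {w0}")
    if dt <= 0:
        raise ValueError(f"time step must be positive, got {dt}")
    return w0 * (1.0 + growth_rate(T, params) * dt)


def simulate_trajectory(
    temps, w0: float, params: GrowthModelParams, dt: float
) -> np.ndarray:
    """Compound dry weight through a time-ordered temperature series.

    ``temps`` holds one temperature (K) per step of length ``dt`` (day);
    hourly series use dt = 1/24.  Returns an array of length ``len(temps)+1``
    whose first element is ``w0``.
    """
    temps = np.asarray(temps, dtype=float)
    if w0 <= 0:
        raise ValueError(f"initial dry weight must be positive, got {w0}")
    if dt <= 0:
        raise ValueError(f"time step must be positive, got {dt}")
    if temps.size == 0:
        return np.array([w0], dtype=float)
    rates = growth_rate(temps, params)
    # W_n = w0 * prod(1 + r_i * dt): cumulative product of per-step factors
    factors = np.concatenate([[1.0], np.cumprod(1.0 + rates * dt)])
    return w0 * factors


def rmse(pred, obs) -> float:
    """Root mean squared error between predictions and observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError(
            f"prediction/observation shapes must match and be non-empty, "
            f"got {pred.shape} vs {obs.shape}"
        )
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def r_squared(pred, obs) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Equals 1 for a perfect fit and may be negative for fits worse than the
    observation mean.  Undefined (raises) when the observations have zero
    variance.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or obs.size < 2:
        raise ValueError("need >= 2 paired observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observations have zero variance; R^2 undefined")
    ss_res = float(np.sum((pred - obs) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class ChamberDataset:
    """Dry-weight observations from one two-temperature growth-chamber regime.

    ``days`` are days post-transplant (strictly increasing); ``dry_weights``
    are g/plant.  The default 9 h high / 15 h low split mirrors the classic
    chamber protocol.
    """

    regime: str
    t_high: float  # K
    t_low: float  # K
    days: tuple
    dry_weights: tuple
    h_high: float = 9.0
    h_low: float = 15.0

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        dw = np.asarray(self.dry_weights, dtype=float)
        if days.size != dw.size or days.size == 0:
            raise ValueError("days and dry_weights must be equal-length, non-empty")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(dw <= 0):
            raise ValueError("dry weights must be positive")
        if abs(self.h_high + self.h_low - 24.0) > 1e-9:
            raise InvalidDesignError("hours at high and low must sum to 24")
        object.__setattr__(self, "days", tuple(float(d) for d in days))
        object.__setattr__(self, "dry_weights", tuple(float(w) for w in dw))

    @property
    def day_temperature(self) -> float:
        """Hour-weighted daily mean temperature of the regime (K)."""
        return weighted_day_temperature(self.t_high, self.t_low, self.h_high, self.h_low)


@dataclass(frozen=True)
class FitResult:
    params: GrowthModelParams
    rmse: float  # g/plant, pooled over all regimes
    r2: float
    n_obs: int
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if self.r2 > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")


def predict_chamber(dataset: ChamberDataset, params: GrowthModelParams) -> np.ndarray:
    """Model-predicted dry weight at the dataset's sampling days.

    The model compounds daily at the regime's weighted day temperature; the
    regime's (unobserved) initial dry weight is a conditionally linear
    nuisance and is profiled out: given the rate, the least-squares scale
    against the observations is closed-form, so no single noisy observation
    anchors the curve.
    """
    r = growth_rate(dataset.day_temperature, params)
    days = np.asarray(dataset.days, dtype=float)
    obs = np.asarray(dataset.dry_weights, dtype=float)
    growth = (1.0 + r) ** (days - days[0])
    scale = float(growth @ obs) / float(growth @ growth)
    return scale * growth


PARAM_NAMES = ("A", "k", "S", "H")


def _pooled_residuals(x: np.ndarray, datasets: Sequence[ChamberDataset]) -> np.ndarray:
    params = GrowthModelParams.from_array(x)
    res = []
    for ds in datasets:
        pred = predict_chamber(ds, params)
        res.append(pred - np.asarray(ds.dry_weights))
    return np.concatenate(res)


def pooled_rmse(datasets: Sequence[ChamberDataset], params: GrowthModelParams) -> float:
    """RMSE pooled over all observation points of all regimes, equal weight."""
    res = _pooled_residuals(params.as_array(), datasets)
    return float(np.sqrt(np.mean(res**2)))


def _regime_rate_estimates(datasets: Sequence[ChamberDataset]) -> tuple[np.ndarray, np.ndarray]:
    """Per-regime (T, r) from the log-linear dry-weight slope.

    Under daily compounding log W is linear in day with slope log(1 + r),
    so a least-squares line through (day, log W) estimates each regime's
    relative growth rate directly.
    """
    temps, rates = [], []
    for ds in datasets:
        days = np.asarray(ds.days)
        logw = np.log(np.asarray(ds.dry_weights))
        slope = np.polyfit(days, logw, 1)[0]
        r = math.expm1(slope)
        if r > 0:
            temps.append(ds.day_temperature)
            rates.append(r)
    return np.asarray(temps), np.asarray(rates)


def _log_rate_residuals(x: np.ndarray, temps: np.ndarray, log_r: np.ndarray) -> np.ndarray:
    A, k, S, H = x
    pred = math.log(max(A, 1e-300)) + np.log(temps) - k / temps - np.logaddexp(0.0, S - H / temps)
    return pred - log_r


def _limb_start(
    temps: np.ndarray, rates: np.ndarray, init: GrowthModelParams
) -> GrowthModelParams | None:
    """Data-driven start: Arrhenius limb below the empirical rate peak,
    inactivation limb above it.

    The inactivation term creates two degenerate branches (saturated
    everywhere / negligible everywhere) that trap purely local fits started
    in the wrong branch; splitting the rate curve at its peak and solving
    each limb linearly lands the start in the correct branch.
    """
    if rates.size < 4:
        return None
    order = np.argsort(temps)
    temps, rates = temps[order], rates[order]
    peak = int(np.argmax(rates))
    rising = slice(0, max(peak + 1, 2))
    if rising.stop - rising.start < 2:
        return None
    # log r - log T = log A - k/T on the rising limb (denominator ~ 1)
    coef = np.polyfit(1.0 / temps[rising], np.log(rates[rising]) - np.log(temps[rising]), 1)
    k0, logA0 = -float(coef[0]), float(coef[1])
    if k0 <= 0:
        return None
    # attenuation on the declining limb: log(exp(d) - 1) = S - H/T
    decline_T, decline_y = [], []
    for T, r in zip(temps[peak + 1 :], rates[peak + 1 :]):
        d = logA0 + math.log(T) - k0 / T - math.log(r)
        if d > 1e-8:
            decline_T.append(T)
            decline_y.append(math.log(math.expm1(d)))
    if len(decline_T) >= 2:
        coef = np.polyfit(1.0 / np.asarray(decline_T), np.asarray(decline_y), 1)
        H0, S0 = -float(coef[0]), float(coef[1])
        if H0 <= 0:
            S0, H0 = init.S, init.H
    else:
        S0, H0 = init.S, init.H
    try:
        return GrowthModelParams(A=math.exp(logA0), k=k0, S=S0, H=H0)
    except (ValueError, OverflowError):
        return None


def _bounded_ls(fun, x0, args, lower, free_mask):
    """Least squares over the free subset of (A, k, S, H)."""
    x_full = np.array(x0, dtype=float)
    idx = np.flatnonzero(free_mask)

    def wrapped(xf):
        x = x_full.copy()
        x[idx] = xf
        return fun(x, *args)

    sol = least_squares(
        wrapped,
        x_full[idx],
        bounds=(lower[idx], np.full(idx.size, np.inf)),
        x_scale=np.maximum(np.abs(x_full[idx]), 1e-3),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=10_000,
    )
    x_out = x_full.copy()
    x_out[idx] = sol.x
    return x_out, sol


def fit_growth_params(
    datasets: Sequence[ChamberDataset],
    init: GrowthModelParams = PUBLISHED_TOBACCO_PARAMS,
    free: Sequence[str] = PARAM_NAMES,
) -> FitResult:
    """Fit (A, k, S, H) by minimizing the pooled RMSE over chamber regimes.

    Bounded local least squares (trust-region reflective), deterministic
    given ``init``.  Because S and H enter through exp(S - H/T), the pooled
    dry-weight residual surface has near-flat plateaus far from the optimum;
    the fit therefore first matches the model to per-regime rate estimates
    on the log scale (where S and H have unit-scale gradients) and then
    polishes on the pooled dry-weight residuals, keeping whichever start
    ends best.  ``free`` restricts the fit to a parameter subset for
    profile fits.  The result never has a pooled RMSE above the initial
    guess's: if the solver fails to improve, the initial guess is returned
    with ``converged=False``.
    """
    datasets = list(datasets)
    if not datasets or any(len(ds.days) < 2 for ds in datasets):
        raise ValueError("need >= 1 dataset with >= 2 observations each")
    unknown = set(free) - set(PARAM_NAMES)
    if unknown or not free:
        raise ValueError(f"free must be a non-empty subset of {PARAM_NAMES}, got {free}")
    free_mask = np.array([name in free for name in PARAM_NAMES])

    x0 = init.as_array()
    lower = np.array([1e-12, 1e-6, -np.inf, 1e-6])

    starts = [x0]
    temps, rates = _regime_rate_estimates(datasets)
    if np.all(free_mask):
        limb = _limb_start(temps, rates, init)
        if limb is not None:
            starts.append(limb.as_array())
    if rates.size >= 2:
        for s in list(starts):
            x_rate, _ = _bounded_ls(
                _log_rate_residuals, s, (temps, np.log(rates)), lower, free_mask
            )
            starts.append(x_rate)

    best_x, best_sol = None, None
    for start in starts:
        x_fit, sol = _bounded_ls(_pooled_residuals, start, (datasets,), lower, free_mask)
        cost = float(np.sqrt(np.mean(sol.fun**2)))
        if best_x is None or cost < best_cost:
            best_x, best_sol, best_cost = x_fit, sol, cost

    fitted = GrowthModelParams.from_array(best_x)
    rmse_init = pooled_rmse(datasets, init)
    rmse_fit = pooled_rmse(datasets, fitted)
    converged = bool(best_sol.success)
    message = best_sol.message
    if rmse_fit > rmse_init:
        fitted, rmse_fit = init, rmse_init
        converged = False
        message = f"solver did not improve on the initial guess: {best_sol.message}"
        warnings.warn("growth-model fit failed to improve on init", RuntimeWarning)

    obs = np.concatenate([np.asarray(ds.dry_weights) for ds in datasets])
    pred = np.concatenate([predict_chamber(ds, fitted) for ds in datasets])
    return FitResult(
        params=fitted,
        rmse=rmse_fit,
        r2=r_squared(pred, obs),
        n_obs=int(obs.size),
        converged=converged,
        message=message,
    )


def read_chamber_csv(path) -> list[ChamberDataset]:
    """Read chamber regimes from CSV (regime, T_high_C, T_low_C, day, dry_weight_g)."""
    df = pd.read_csv(path)
    required = {"regime", "T_high_C", "T_low_C", "day", "dry_weight_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chamber CSV missing columns: {sorted(missing)}")
    out = []
    for regime, grp in df.groupby("regime", sort=True):
        grp = grp.sort_values("day")
        out.append(
            ChamberDataset(
                regime=str(regime),
                t_high=float(grp["T_high_C"].iloc[0]) + KELVIN_OFFSET,
                t_low=float(grp["T_low_C"].iloc[0]) + KELVIN_OFFSET,
                days=tuple(grp["day"].astype(float)),
                dry_weights=tuple(grp["dry_weight_g"].astype(float)),
            )
        )
    return out


def write_chamber_csv(datasets: Sequence[ChamberDataset], path) -> None:
    rows = []
    for ds in datasets:
        for d, w in zip(ds.days, ds.dry_weights):
            rows.append(
                {
                    "regime": ds.regime,
                    "T_high_C": ds.t_high - KELVIN_OFFSET,
                    "T_low_C": ds.t_low - KELVIN_OFFSET,
                    "day": d,
                    "dry_weight_g": w,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
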