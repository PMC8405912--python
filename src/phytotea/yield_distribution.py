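"""Monthly field-yield prediction and four-parameter beta fitting.

Hourly air temperature drives the growth model over a fixed 27-day window
starting at the first hour of each month (day 27 after seedling emergence;
with a 15-day germination period this corresponds to day 42 post seeding —
a bookkeeping offset only).  Monthly dry weights are normalized by their
maximum and the normalized sample is summarized by a scaled (four-parameter)
beta distribution used downstream as the field-growth-yield assumption.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad

from .growth_model import KELVIN_OFFSET, GrowthModelParams, simulate_trajectory

__all__ = [
    "HourlyWeatherSeries",
    "ScaledBetaParams",
    "MissingHoursError",
    "read_weather_csv",
    "write_weather_csv",
    "monthly_dry_weight",
    "build_yield_table",
    "normalize_by_max",
    "fit_scaled_beta",
    "scaled_beta_mean",
    "scaled_beta_dist",
    "relative_sd",
    "yield_summary",
    "GROWTH_WINDOW_DAYS",
    "SEEDLING_DRY_WEIGHT_G",
    "GERMINATION_DAYS",
]

logger = logging.getLogger(__name__)

GROWTH_WINDOW_DAYS = 27
SEEDLING_DRY_WEIGHT_G = 0.5  # g/plant initial dry weight at emergence
GERMINATION_DAYS = 15  # labeled offset: day 27 post-emergence = day 42 post-seeding
MAX_GAP_HOURS = 3  # longest weather gap bridged by linear interpolation


class MissingHoursError(ValueError):
    """A month's hourly record has gaps too long to interpolate."""


@dataclass
class HourlyWeatherSeries:
    """Hourly air temperatures in kelvin with a strictly increasing time index.

    ``temps`` is a pandas Series indexed by timestamps at (nominally) hourly
    cadence; synthetic series may skip Feb 29.
    """

    temps: pd.Series
    source: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.temps.index, pd.DatetimeIndex):
            raise TypeError("temps must be indexed by a DatetimeIndex")
        if len(self.temps) == 0:
            raise ValueError("weather series is empty")
        if not self.temps.index.is_monotonic_increasing or self.temps.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temps)


def read_weather_csv(path, source: str = "") -> HourlyWeatherSeries:
    """Read an hourly weather export with columns ``timestamp`` (ISO-8601) and ``temp_C``."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if "temp_C" not in df.columns:
        raise ValueError("weather CSV must have columns timestamp, temp_C")
    s = pd.Series(
        df["temp_C"].astype(float).to_numpy() + KELVIN_OFFSET,
        index=pd.DatetimeIndex(df["timestamp"]),
        name="temp_K",
    )
    return HourlyWeatherSeries(temps=s.sort_index(), source=source or str(path))


def write_weather_csv(weather: HourlyWeatherSeries, path) -> None:
    pd.DataFrame(
        {
            "timestamp": weather.temps.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "temp_C": weather.temps.to_numpy() - KELVIN_OFFSET,
        }
    ).to_csv(path, index=False)


def _window_temps(weather: HourlyWeatherSeries, year: int, month: int) -> np.ndarray:
    """Extract the 27*24 hourly temperatures for one month's growth window."""
    start = pd.Timestamp(year=year, month=month, day=1, hour=0)
    idx = pd.date_range(start, periods=GROWTH_WINDOW_DAYS * 24, freq="h")
    window = weather.temps.reindex(idx)
    if window.isna().any():
        # bridge short sensor dropouts only
        filled = window.interpolate(method="linear", limit=MAX_GAP_HOURS, limit_area="inside")
        if filled.isna().any():
            n = int(window.isna().sum())
            raise MissingHoursError(
                f"{year}-{month:02d}: {n} missing hours exceed the "
                f"{MAX_GAP_HOURS}-hour interpolation limit"
            )
        window = filled
    return window.to_numpy()


def monthly_dry_weight(
    weather: HourlyWeatherSeries,
    year: int,
    month: int,
    params: GrowthModelParams,
    w0: float = SEEDLING_DRY_WEIGHT_G,
) -> float:
    """Predicted dry weight (g/plant) 27 days after month start.

    Simulates hourly growth from ``w0`` over exactly 27*24 steps beginning at
    the first hour of the first day of the month.
    """
    temps = _window_temps(weather, year, month)
    traj = simulate_trajectory(temps, w0, params, dt=1.0 / 24.0)
    return float(traj[-1])


def build_yield_table(
    weather: HourlyWeatherSeries,
    years,
    params: GrowthModelParams,
    w0: float = SEEDLING_DRY_WEIGHT_G,
) -> pd.DataFrame:
    """Monthly predicted yields: one row per (year, month) with complete data.

    Incomplete months are skipped with a logged warning rather than failing
    the whole table.
    """
    rows = []
    for year in years:
        for month in range(1, 13):
            try:
                dw = monthly_dry_weight(weather, year, month, params, w0=w0)
            except MissingHoursError as exc:
                logger.warning("skipping %s", exc)
                continue
            rows.append({"year": int(year), "month": month, "yield_g": dw})
    if not rows:
        raise ValueError("no usable months in the requested years")
    return pd.DataFrame(rows)


def normalize_by_max(table) -> np.ndarray:
    """Normalize yields by their maximum so the largest value is exactly 1."""
    if isinstance(table, pd.DataFrame):
        values = table["yield_g"].to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
    if values.size == 0:
        raise ValueError("empty yield table")
    top = values.max()
    if top <= 0:
        raise ValueError("maximum yield must be positive")
    return values / top


@dataclass(frozen=True)
class ScaledBetaParams:
    """Four-parameter (scaled) beta distribution on [minimum, maximum]."""

    alpha: float
    beta: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("shape parameters must be positive")
        if not self.minimum < self.maximum:
            raise ValueError("minimum must be below maximum")
        if not all(
            math.isfinite(v) for v in (self.alpha, self.beta, self.minimum, self.maximum)
        ):
            raise ValueError("parameters must be finite")


def scaled_beta_dist(params: ScaledBetaParams):
    """Frozen scipy distribution for a ScaledBetaParams."""
    return stats.beta(
        params.alpha, params.beta, loc=params.minimum, scale=params.maximum - params.minimum
    )


def scaled_beta_mean(params: ScaledBetaParams) -> float:
    """Closed-form mean: min + (max - min) * alpha / (alpha + beta)."""
    frac = params.alpha / (params.alpha + params.beta)
    return params.minimum + (params.maximum - params.minimum) * frac


def scaled_beta_mean_numeric(params: ScaledBetaParams) -> float:
    """Mean via numerical integration of x*pdf(x); cross-check for the closed form."""
    d = scaled_beta_dist(params)
    val, _ = quad(lambda x: x * d.pdf(x), params.minimum, params.maximum, limit=200)
    return float(val)


def fit_scaled_beta(values) -> ScaledBetaParams:
    """Fit a four-parameter beta to normalized yields in (0, 1].

    The maximum is anchored at 1 (the data are max-normalized, so the upper
    support endpoint is known).  The minimum is set just below the sample
    minimum — endpoint MLE for a bounded distribution is non-regular, and a
    small margin keeps the likelihood finite — then the two shape parameters
    are estimated by maximum likelihood with the support held fixed.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError(f"need >= 10 values to fit, got {x.size}")
    if np.any(x <= 0) or np.any(x > 1 + 1e-12):
        raise ValueError("values must lie in (0, 1]")
    if np.std(x) < 1e-12:
        raise ValueError("degenerate sample: zero variance")

    maximum = 1.0
    smin = float(x.min())
    margin = 0.01 * (maximum - smin)
    minimum = smin - margin
    scale = maximum - minimum

    # map onto (0, 1); observations at the anchored maximum are pulled half a
    # plotting position inside so the likelihood stays finite
    eps = 0.5 / x.size
    z = np.clip((x - minimum) / scale, eps, 1.0 - eps)
    m, v = z.mean(), z.var()
    common = max(m * (1 - m) / max(v, 1e-12) - 1.0, 0.2)
    a0, b0 = max(m * common, 0.05), max((1 - m) * common, 0.05)

    a, b, _, _ = stats.beta.fit(z, a0, b0, floc=0.0, fscale=1.0)
    return ScaledBetaParams(alpha=float(a), beta=float(b), minimum=minimum, maximum=maximum)


def relative_sd(mean: float, sd: float) -> float:
    """Relative standard deviation (coefficient of variation) in percent."""
    if mean == 0:
        raise ValueError("relative SD undefined for zero mean")
    return 100.0 * sd / mean


def yield_summary(table: pd.DataFrame) -> dict:
    """Mean, SD and relative SD (%) of the monthly yields."""
    y = table["yield_g"].to_numpy(dtype=float)
    mean = float(y.mean())
    sd = float(y.std(ddof=1))
    return {"mean_g": mean, "sd_g": sd, "rsd_percent": relative_sd(mean, sd), "n": int(y.size)}
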