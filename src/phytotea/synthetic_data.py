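"""Synthetic inputs for the full pipeline: weather, chamber data, fixtures.

The weather generator emulates a subtropical (Homestead-FL-like) hourly
temperature record with a seasonal sinusoid, a diurnal sinusoid and AR(1)
noise — the simplest stochastic process carrying the features the yield
model responds to.  It is not a climatological model.

The chamber generator produces dry-weight observations from the forward
growth model itself (plus optional Gaussian noise), which makes exact
parameter-recovery tests possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assumptions import default_registry, save_registry
from .growth_model import (
    KELVIN_OFFSET,
    ChamberDataset,
    GrowthModelParams,
    growth_rate,
    weighted_day_temperature,
    write_chamber_csv,
)
from .yield_distribution import (
    HourlyWeatherSeries,
    ScaledBetaParams,
    build_yield_table,
    fit_scaled_beta,
    normalize_by_max,
    write_weather_csv,
)

__all__ = [
    "ClimateProfile",
    "SyntheticExperimentDesign",
    "SYNTHETIC_TRUE_PARAMS",
    "synth_weather",
    "synth_chamber_data",
    "yield_pipeline_fixture",
    "write_fixtures",
]

#: Ground-truth growth parameters used by the synthetic generators.  Chosen so
#: the relative growth rate is horticulturally plausible (~0.15 day^-1 near
#: 297 K, optimum near 296.5 K, declining above), giving 27-day yields of
#: ~20-26 g/plant from a 0.5 g seedling — the scale field studies report.
SYNTHETIC_TRUE_PARAMS = GrowthModelParams(A=0.45, k=1992.0, S=80.0, H=24400.0)


@dataclass(frozen=True)
class ClimateProfile:
    """Sinusoids-plus-AR(1) description of an hourly temperature climate.

    Defaults emulate Homestead, FL: warm annual mean (~24 C), mild seasons,
    a few kelvin of diurnal swing, and weather-band autocorrelated noise.
    """

    mean_K: float = 297.0
    seasonal_amp_K: float = 5.0
    diurnal_amp_K: float = 4.0
    ar_coeff: float = 0.8
    noise_sd_K: float = 1.5
    seasonal_peak_doy: float = 196.0  # mid-July
    diurnal_peak_hour: float = 15.0

    def __post_init__(self) -> None:
        if self.seasonal_amp_K < 0 or self.diurnal_amp_K < 0 or self.noise_sd_K < 0:
            raise ValueError("amplitudes and noise sd must be non-negative")
        if abs(self.ar_coeff) >= 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")


def synth_weather(
    profile: ClimateProfile = ClimateProfile(),
    years: int = 3,
    seed: int = 0,
    start_year: int = 2017,
) -> HourlyWeatherSeries:
    """Generate ``years`` synthetic years of hourly temperatures (8760 h each).

    Synthetic years are 365 days: Feb 29 is skipped in leap years, so the
    record length is exactly 8760 * years.  Deterministic per seed.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    idx = pd.date_range(
        start=pd.Timestamp(year=start_year, month=1, day=1),
        end=pd.Timestamp(year=start_year + years - 1, month=12, day=31, hour=23),
        freq="h",
    )
    idx = idx[~((idx.month == 2) & (idx.day == 29))]
    n = len(idx)
    assert n == 8760 * years

    doy = idx.dayofyear.to_numpy(dtype=float)
    # after dropping Feb 29, renumber trailing days so the seasonal phase is smooth
    leap = idx.is_leap_year & (idx.dayofyear > 59)
    doy[leap] -= 1.0
    hour = idx.hour.to_numpy(dtype=float)

    seasonal = profile.seasonal_amp_K * np.cos(
        2 * np.pi * (doy - profile.seasonal_peak_doy) / 365.0
    )
    diurnal = profile.diurnal_amp_K * np.cos(
        2 * np.pi * (hour - profile.diurnal_peak_hour) / 24.0
    )

    rng = np.random.default_rng(seed)
    noise = np.zeros(n)
    if profile.noise_sd_K > 0:
        eps = rng.normal(0.0, profile.noise_sd_K, size=n)
        phi = profile.ar_coeff
        # stationary start, then AR(1) recursion
        noise[0] = eps[0] / np.sqrt(1 - phi**2)
        for t in range(1, n):
            noise[t] = phi * noise[t - 1] + eps[t]

    temps = pd.Series(profile.mean_K + seasonal + diurnal + noise, index=idx, name="temp_K")
    return HourlyWeatherSeries(temps=temps, source=f"synthetic({seed})")


def _default_regimes() -> tuple:
    """Ten (high, low) chamber set-points in kelvin.

    Weighted day temperatures span 13-37 C, deliberately bracketing the
    growth optimum so both the Arrhenius limb and the inactivation limb of
    the rate curve are sampled.
    """
    pairs_c = [
        (18, 10), (22, 14), (26, 18), (30, 22), (34, 26),
        (38, 30), (40, 32), (28, 16), (36, 24), (42, 34),
    ]
    return tuple((h + KELVIN_OFFSET, l + KELVIN_OFFSET) for h, l in pairs_c)


@dataclass(frozen=True)
class SyntheticExperimentDesign:
    """Design of a synthetic growth-chamber experiment.

    Ten two-temperature regimes by default (9 h high / 15 h low), sampled on
    a weekly-ish grid, generated from ``true_params`` with additive Gaussian
    dry-weight noise.
    """

    regimes: tuple = field(default_factory=_default_regimes)
    sampling_days: tuple = (3.0, 8.0, 13.0, 17.0, 22.0, 27.0)
    noise_sd: float = 0.5  # g/plant, between-plant biological variation
    true_params: GrowthModelParams = SYNTHETIC_TRUE_PARAMS
    w0: float = 0.5  # g/plant at transplant (day 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regimes:
            raise ValueError("need at least one regime")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def synth_chamber_data(design: SyntheticExperimentDesign) -> list[ChamberDataset]:
    """Generate chamber datasets from the forward model at weighted day temperature."""
    rng = np.random.default_rng(design.seed)
    days = np.asarray(design.sampling_days, dtype=float)
    out = []
    for i, (t_high, t_low) in enumerate(design.regimes):
        t_day = weighted_day_temperature(t_high, t_low)
        r = growth_rate(t_day, design.true_params)
        w = design.w0 * (1.0 + r) ** days
        if design.noise_sd > 0:
            w = w + rng.normal(0.0, design.noise_sd, size=w.size)
            w = np.maximum(w, 1e-3)  # dry weights stay positive
        out.append(
            ChamberDataset(
                regime=f"regime_{i + 1:02d}",
                t_high=t_high,
                t_low=t_low,
                days=tuple(days),
                dry_weights=tuple(w),
            )
        )
    return out


def yield_pipeline_fixture(
    seed: int = 0,
    params: GrowthModelParams = SYNTHETIC_TRUE_PARAMS,
) -> tuple[HourlyWeatherSeries, pd.DataFrame, ScaledBetaParams]:
    """End-to-end smoke fixture: 3 synthetic years -> 36 monthly yields -> beta fit."""
    weather = synth_weather(seed=seed)
    years = sorted(weather.temps.index.year.unique())
    table = build_yield_table(weather, years, params)
    beta = fit_scaled_beta(normalize_by_max(table))
    return weather, table, beta


def write_fixtures(outdir, seed: int = 42) -> dict:
    """Write weather CSV, chamber CSV and the default assumption registry YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weather = synth_weather(seed=seed)
    chambers = synth_chamber_data(SyntheticExperimentDesign(noise_sd=0.5, seed=seed))
    paths = {
        "weather": outdir / "weather.csv",
        "chambers": outdir / "chambers.csv",
        "registry": outdir / "assumptions.yaml",
    }
    write_weather_csv(weather, paths["weather"])
    write_chamber_csv(chambers, paths["chambers"])
    save_registry(default_registry(), paths["registry"])
    return paths
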