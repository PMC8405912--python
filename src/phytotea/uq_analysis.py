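"""Post-simulation uncertainty analyses.

Scenario comparison (Welch t and two-sample Kolmogorov–Smirnov), normality
assessment (normal QQ points), univariate sensitivity (tornado and spider
sweeps through the assumption quantiles) and contribution to variance by
signed, normalized squared Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assumptions import AssumptionSpec, _trunc_cdf_bounds, frozen_dist

__all__ = [
    "ComparisonResult",
    "SensitivityResult",
    "VarianceContribution",
    "compare_scenarios",
    "qq_points",
    "assumption_quantile",
    "tornado",
    "spider",
    "contribution_to_variance",
    "extremal_trials",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample comparison of one forecast between scenarios."""

    forecast: str
    t_statistic: float
    t_pvalue: float
    ks_statistic: float
    ks_pvalue: float
    n_a: int
    n_b: int
    t_defined: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.ks_statistic <= 1:
            raise ValueError("KS D must lie in [0, 1]")
        for p in (self.t_pvalue, self.ks_pvalue):
            if not (np.isnan(p) or 0 <= p <= 1):
                raise ValueError("p-values must lie in [0, 1]")


def compare_scenarios(a, b, forecast: str = "") -> ComparisonResult:
    """Welch two-sample t test and asymptotic two-sample KS test.

    When both samples have zero variance the t statistic is undefined; the
    result is flagged (t = 0 with ``t_defined=False`` for identical
    constants, NaN otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")

    if a.std() == 0 and b.std() == 0:
        t_stat = 0.0 if a.mean() == b.mean() else float("nan")
        t_p, t_defined = float("nan"), False
    else:
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
        t_stat, t_p, t_defined = float(t_stat), float(t_p), True

    ks = stats.ks_2samp(a, b, method="asymp")
    return ComparisonResult(
        forecast=forecast,
        t_statistic=t_stat,
        t_pvalue=t_p,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
        t_defined=t_defined,
    )


def qq_points(sample) -> np.ndarray:
    """Normal QQ points: (standard-normal quantile, ordered sample value).

    Plotting positions (i - 0.5)/n.  Returns an (n, 2) array; rendering is
    left to the caller.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for QQ points")
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return np.column_stack([theo, x])


def assumption_quantile(spec: AssumptionSpec, q: float) -> float:
    """Quantile of an assumption distribution, honouring truncation."""
    if not 0 < q < 1:
        raise ValueError("quantile must be in (0, 1)")
    d = frozen_dist(spec)
    lo_u, hi_u = _trunc_cdf_bounds(spec)
    return float(d.ppf(lo_u + q * (hi_u - lo_u)))


@dataclass(frozen=True)
class SensitivityResult:
    """Univariate sensitivity sweep output.

    ``table`` rows are sorted by descending swing for tornado sweeps; for
    spider sweeps ``curves`` maps each parameter to its forecast values over
    the percentile grid.
    """

    forecast: str
    table: pd.DataFrame  # parameter, low, high, swing (tornado)
    curves: Optional[pd.DataFrame] = None  # index: percentile, columns: parameters
    failures: tuple = ()


def tornado(
    model: Callable[[Mapping[str, float]], float],
    base_inputs: Mapping[str, float],
    registry: Sequence[AssumptionSpec],
    percentiles: tuple = (0.10, 0.90),
) -> SensitivityResult:
    """One-at-a-time sweep of each assumption to its low/high quantile.

    ``model`` maps a full input dict to a scalar forecast; all other inputs
    stay at their base values.  Parameters are ranked by swing
    |high - low|.  A model failure at an extreme flags the parameter
    instead of aborting the sweep.
    """
    lo_q, hi_q = percentiles
    if not (0 < lo_q < hi_q < 1):
        raise ValueError("percentiles must satisfy 0 < lo < hi < 1")
    rows, failures = [], []
    for spec in registry:
        vals = {}
        try:
            for tag, q in (("low", lo_q), ("high", hi_q)):
                inputs = dict(base_inputs)
                inputs[spec.name] = assumption_quantile(spec, q)
                vals[tag] = float(model(inputs))
        except Exception as exc:  # model failure at an extreme
            failures.append((spec.name, repr(exc)))
            continue
        rows.append(
            {
                "parameter": spec.name,
                "low": vals["low"],
                "high": vals["high"],
                "swing": abs(vals["high"] - vals["low"]),
            }
        )
    table = pd.DataFrame(rows, columns=["parameter", "low", "high", "swing"])
    table = table.sort_values(
        ["swing", "parameter"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return SensitivityResult(forecast="", table=table, failures=tuple(failures))


def spider(
    model: Callable[[Mapping[str, float]], float],
    base_inputs: Mapping[str, float],
    registry: Sequence[AssumptionSpec],
    grid: Sequence[float] = tuple(np.arange(0.05, 0.96, 0.05)),
) -> SensitivityResult:
    """Forecast value per parameter over a percentile grid (spider chart data)."""
    grid = [float(g) for g in grid]
    if any(not 0 < g < 1 for g in grid):
        raise ValueError("grid percentiles must be in (0, 1)")
    curves, failures = {}, []
    for spec in registry:
        vals = []
        try:
            for q in grid:
                inputs = dict(base_inputs)
                inputs[spec.name] = assumption_quantile(spec, q)
                vals.append(float(model(inputs)))
        except Exception as exc:
            failures.append((spec.name, repr(exc)))
            continue
        curves[spec.name] = vals
    frame = pd.DataFrame(curves, index=pd.Index(grid, name="percentile"))
    swing = frame.max() - frame.min()
    table = (
        pd.DataFrame({"parameter": frame.columns, "swing": swing.to_numpy()})
        .sort_values(["swing", "parameter"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return SensitivityResult(forecast="", table=table, curves=frame, failures=tuple(failures))


@dataclass(frozen=True)
class VarianceContribution:
    """Signed contribution-to-variance shares (%), one per input parameter."""

    shares: pd.Series  # index: parameter, values: signed %
    rho: pd.Series  # Spearman correlations behind the shares

    def __post_init__(self) -> None:
        total = float(self.shares.abs().sum())
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"absolute shares must sum to 100, got {total}")


def contribution_to_variance(inputs: pd.DataFrame, forecast) -> VarianceContribution:
    """Contribution to variance by rank correlation.

    share_i = sign(rho_i) * rho_i^2 / sum_j rho_j^2 * 100, with rho the
    Spearman correlation between each input column and the forecast.
    """
    y = np.asarray(forecast, dtype=float)
    if len(inputs) != y.size or y.size < 30:
        raise ValueError("need matching inputs/forecast with n >= 30")
    ok = np.isfinite(y)
    y = y[ok]
    rho = {}
    for col in inputs.columns:
        r = stats.spearmanr(inputs[col].to_numpy()[ok], y).statistic
        rho[col] = 0.0 if np.isnan(r) else float(r)
    rho = pd.Series(rho)
    denom = float((rho**2).sum())
    if denom == 0:
        raise ValueError("all rank correlations are zero; contribution undefined")
    shares = np.sign(rho) * rho**2 / denom * 100.0
    order = shares.abs().sort_values(ascending=False).index
    return VarianceContribution(shares=shares.loc[order], rho=rho.loc[order])


def extremal_trials(
    records: pd.DataFrame, forecast: str
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Rows of the minimum, nearest-to-mean, and maximum forecast trials.

    NaN forecasts are ignored; ties break to the lowest row position.
    """
    y = records[forecast]
    valid = records[y.notna() & np.isfinite(y)]
    if valid.empty:
        raise ValueError(f"no valid values for forecast {forecast!r}")
    yv = valid[forecast].to_numpy(dtype=float)
    i_min = int(np.argmin(yv))
    i_max = int(np.argmax(yv))
    i_mean = int(np.argmin(np.abs(yv - yv.mean())))
    return valid.iloc[i_min], valid.iloc[i_mean], valid.iloc[i_max]
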