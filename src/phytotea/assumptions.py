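"""Assumption-distribution registry and correlated Monte Carlo sampler.

Each uncertain process input carries an *assumption distribution* — one of
four families (logistic, triangular, four-parameter beta, uniform) with
optional truncation.  Rank correlation between assumptions, when requested,
is induced by Iman–Conover-style reordering, which preserves the marginals
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "AssumptionSpec",
    "CorrelationSpec",
    "TrialInputMatrix",
    "FAMILIES",
    "default_registry",
    "frozen_dist",
    "assumption_mean",
    "normalize_to_mean",
    "sample_assumption",
    "sample_trials",
    "save_registry",
    "load_registry",
]

FAMILIES = ("logistic", "triangular", "beta4", "uniform")

# Base-case process values behind the shipped registry.  Values without a
# public source are working-process-knowledge placeholders, overridable via
# a registry file; see docs/methods.md.
BASE_EXPRESSION_G_PER_KG = 1.50  # base-case expression level
EXPRESSION_CV = 0.30  # stand-in CV for the expression histogram fit
HARVESTER_SPEED_KMH = (1.0, 10.0)  # harvester ground-speed range
HARVEST_PASS_KM = 10.0  # field pass length driving harvest-time bounds


@dataclass(frozen=True)
class AssumptionSpec:
    """One uncertain input: distribution family, parameters, units, truncation.

    Family parameter conventions:
      - logistic: (location, scale); mean = location
      - triangular: (minimum, mode, maximum)
      - beta4: (alpha, beta, minimum, maximum)
      - uniform: (minimum, maximum)

    ``truncation`` is an optional (lo, hi) pair (either side may be None);
    sampling is by inverse-CDF restricted to the truncated interval.
    """

    name: str
    family: str
    params: tuple
    units: str = ""
    truncation: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if self.family == "logistic":
            if len(p) != 2 or p[1] <= 0:
                raise ValueError(f"logistic needs (loc, scale>0), got {p}")
        elif self.family == "triangular":
            if len(p) != 3 or not (p[0] <= p[1] <= p[2]) or p[0] >= p[2]:
                raise ValueError(f"triangular needs min <= mode <= max, min < max, got {p}")
        elif self.family == "beta4":
            if len(p) != 4 or p[0] <= 0 or p[1] <= 0 or p[2] >= p[3]:
                raise ValueError(f"beta4 needs (a>0, b>0, min<max), got {p}")
        elif self.family == "uniform":
            if len(p) != 2 or p[0] >= p[1]:
                raise ValueError(f"uniform needs min < max, got {p}")
        if self.truncation is not None:
            lo, hi = self.truncation
            lo = None if lo is None else float(lo)
            hi = None if hi is None else float(hi)
            if lo is not None and hi is not None and lo >= hi:
                raise ValueError(f"truncation bounds out of order: {self.truncation}")
            object.__setattr__(self, "truncation", (lo, hi))


def frozen_dist(spec: AssumptionSpec):
    """Frozen scipy.stats distribution for the (untruncated) family."""
    p = spec.params
    if spec.family == "logistic":
        return stats.logistic(loc=p[0], scale=p[1])
    if spec.family == "triangular":
        lo, mode, hi = p
        return stats.triang(c=(mode - lo) / (hi - lo), loc=lo, scale=hi - lo)
    if spec.family == "beta4":
        a, b, lo, hi = p
        return stats.beta(a, b, loc=lo, scale=hi - lo)
    if spec.family == "uniform":
        lo, hi = p
        return stats.uniform(loc=lo, scale=hi - lo)
    raise AssertionError(spec.family)


def _trunc_cdf_bounds(spec: AssumptionSpec) -> tuple:
    d = frozen_dist(spec)
    lo_u, hi_u = 0.0, 1.0
    if spec.truncation is not None:
        lo, hi = spec.truncation
        if lo is not None:
            lo_u = float(d.cdf(lo))
        if hi is not None:
            hi_u = float(d.cdf(hi))
    if not lo_u < hi_u:
        raise ValueError(f"truncation leaves no probability mass for {spec.name}")
    return lo_u, hi_u


def assumption_mean(spec: AssumptionSpec) -> float:
    """Analytic mean of the assumption, accounting for truncation.

    Untruncated families use closed forms; truncated ones integrate
    x * pdf(x) over the truncated support.
    """
    d = frozen_dist(spec)
    if spec.truncation is None:
        return float(d.mean())
    lo_u, hi_u = _trunc_cdf_bounds(spec)
    a, b = float(d.ppf(lo_u)), float(d.ppf(hi_u))
    mass = hi_u - lo_u
    val, _ = quad(lambda x: x * d.pdf(x), a, b, limit=200)
    return float(val / mass)


def normalize_to_mean(spec: AssumptionSpec, target_mean: float) -> AssumptionSpec:
    """Shift or scale a spec so its (truncated) mean equals ``target_mean``.

    Location families (logistic) are shifted; bounded families (uniform,
    triangular, beta4) are scaled multiplicatively, which requires a
    positive current mean.  Truncation bounds move with the distribution.
    """
    current = assumption_mean(spec)
    if math.isclose(current, target_mean, rel_tol=1e-12, abs_tol=1e-12):
        return spec

    if spec.family == "logistic":

        def shifted(delta: float) -> AssumptionSpec:
            loc, scale = spec.params
            trunc = spec.truncation
            if trunc is not None:
                lo, hi = trunc
                trunc = (
                    None if lo is None else lo + delta,
                    None if hi is None else hi + delta,
                )
            return replace(spec, params=(loc + delta, scale), truncation=trunc)

        if spec.truncation is None:
            return shifted(target_mean - current)
        # truncated mean is monotone in the shift; solve numerically
        f = lambda delta: assumption_mean(shifted(delta)) - target_mean
        span = max(abs(target_mean - current) * 4, 4 * spec.params[1], 1e-6)
        delta = brentq(f, target_mean - current - span, target_mean - current + span, xtol=1e-12)
        return shifted(delta)

    if current <= 0:
        raise ValueError(
            f"multiplicative normalization needs a positive mean, got {current} for {spec.name}"
        )
    factor = target_mean / current

    def scaled(fac: float) -> AssumptionSpec:
        if spec.family == "beta4":
            a, b, lo, hi = spec.params
            params = (a, b, lo * fac, hi * fac)
        else:
            params = tuple(v * fac for v in spec.params)
        trunc = spec.truncation
        if trunc is not None:
            lo, hi = trunc
            trunc = (None if lo is None else lo * fac, None if hi is None else hi * fac)
        return replace(spec, params=params, truncation=trunc)

    if spec.truncation is None:
        return scaled(factor)
    f = lambda fac: assumption_mean(scaled(fac)) - target_mean
    return scaled(brentq(f, factor / 10, factor * 10, xtol=1e-14))


def sample_assumption(spec: AssumptionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` samples by (truncated) inverse-CDF transform."""
    if n < 1:
        raise ValueError("n must be >= 1")
    d = frozen_dist(spec)
    lo_u, hi_u = _trunc_cdf_bounds(spec)
    u = rng.uniform(lo_u, hi_u, size=n)
    return np.asarray(d.ppf(u), dtype=float)


def default_registry() -> list[AssumptionSpec]:
    """The base-case assumption registry (nine uncertain inputs).

    - field growth yield: the scaled-beta fit to normalized monthly yields
      (alpha=2.57, beta=4.80 on [0.63, 1]);
    - field growth time: triangular around a 42-day pre-induction cycle;
    - expression level: logistic, mean 1.50 g/kg FW, truncated to keep the
      level positive;
    - harvest time: symmetric beta on the time bounds implied by a
      1-10 km/h harvester speed over a 10 km pass (1-10 h);
    - plate & frame recovery/flux and TFF recovery: triangular around the
      base case;
    - UF/DF (TFF) filtrate flux: triangular at base +/- 25%;
    - CEX recovery: uniform at base +/- 10%.
    """
    t_lo = HARVEST_PASS_KM / HARVESTER_SPEED_KMH[1]
    t_hi = HARVEST_PASS_KM / HARVESTER_SPEED_KMH[0]
    # logistic sd = scale * pi / sqrt(3)
    expr_scale = EXPRESSION_CV * BASE_EXPRESSION_G_PER_KG * math.sqrt(3) / math.pi
    registry = [
        AssumptionSpec(
            "field_growth_yield", "beta4", (2.57, 4.80, 0.63, 1.0), units="fraction of nominal"
        ),
        AssumptionSpec("field_growth_time", "triangular", (35.0, 42.0, 49.0), units="day"),
        AssumptionSpec(
            "expression_level",
            "logistic",
            (BASE_EXPRESSION_G_PER_KG, expr_scale),
            units="g/kg FW",
            truncation=(0.01, 6.0),
        ),
        AssumptionSpec("harvest_time", "beta4", (2.0, 2.0, t_lo, t_hi), units="h"),
        AssumptionSpec("pf_recovery", "triangular", (0.90, 0.95, 1.00), units="fraction"),
        AssumptionSpec("pf_flux", "triangular", (75.0, 100.0, 125.0), units="L/m2/h"),
        AssumptionSpec("tff_recovery", "triangular", (0.85, 0.90, 0.95), units="fraction"),
        AssumptionSpec("tff_flux", "triangular", (37.5, 50.0, 62.5), units="L/m2/h"),
        AssumptionSpec("cex_recovery", "uniform", (0.81, 0.99), units="fraction"),
    ]
    # anchor the truncated expression mean exactly at the base case
    registry = [
        normalize_to_mean(s, BASE_EXPRESSION_G_PER_KG) if s.name == "expression_level" else s
        for s in registry
    ]
    return registry


@dataclass(frozen=True)
class CorrelationSpec:
    """Target rank (Spearman) correlations between named assumption pairs."""

    pairs: tuple  # of (name_i, name_j, rho)

    def __post_init__(self) -> None:
        pairs = []
        for ni, nj, rho in self.pairs:
            rho = float(rho)
            if abs(rho) > 1:
                raise ValueError(f"|rho| must be <= 1 for ({ni}, {nj}), got {rho}")
            pairs.append((str(ni), str(nj), rho))
        object.__setattr__(self, "pairs", tuple(pairs))

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        """Full correlation matrix in the given parameter order; identity off the pairs."""
        idx = {n: i for i, n in enumerate(names)}
        m = np.eye(len(names))
        for ni, nj, rho in self.pairs:
            if ni not in idx or nj not in idx:
                raise KeyError(f"correlation names not in registry: ({ni}, {nj})")
            m[idx[ni], idx[nj]] = m[idx[nj], idx[ni]] = rho
        eig = np.linalg.eigvalsh(m)
        if eig.min() < -1e-10:
            raise ValueError(
                f"correlation matrix not positive semi-definite "
                f"(min eigenvalue {eig.min():.3g}); offending pairs: {self.pairs}"
            )
        return m


@dataclass(frozen=True)
class TrialInputMatrix:
    """Sampled trial inputs: one column per assumption, one row per trial."""

    data: pd.DataFrame
    seed: int

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "trial", np.arange(len(out)))
        out["seed"] = self.seed
        out.to_csv(path, index=False)


def sample_trials(
    registry: Sequence[AssumptionSpec],
    correlation: Optional[CorrelationSpec],
    n: int,
    seed: int,
) -> TrialInputMatrix:
    """Draw an n-trial input matrix; reproducible bit-for-bit given the seed.

    Marginals are sampled independently by inverse CDF.  When a correlation
    spec is given, columns are reordered to the rank pattern of a correlated
    Gaussian copula (Iman–Conover), using the Pearson-from-Spearman mapping
    rho_P = 2 sin(pi * rho_S / 6); marginal values are untouched.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    registry = list(registry)
    names = [s.name for s in registry]
    if len(set(names)) != len(names):
        raise ValueError("duplicate assumption names in registry")
    rng = np.random.default_rng(seed)
    cols = {s.name: sample_assumption(s, n, rng) for s in registry}

    if correlation is not None and correlation.pairs:
        rho_s = correlation.matrix(names)
        rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
        np.fill_diagonal(rho_p, 1.0)
        # nearest-PSD nudge for the elementwise-mapped matrix
        w, v = np.linalg.eigh(rho_p)
        rho_p = (v * np.maximum(w, 1e-10)) @ v.T
        L = np.linalg.cholesky(rho_p)
        z = rng.standard_normal((n, len(names))) @ L.T
        ranks = np.argsort(np.argsort(z, axis=0), axis=0)
        for j, name in enumerate(names):
            cols[name] = np.sort(cols[name])[ranks[:, j]]

    return TrialInputMatrix(data=pd.DataFrame(cols, columns=names), seed=int(seed))


def save_registry(registry: Sequence[AssumptionSpec], path) -> None:
    """Write a registry to YAML (JSON-compatible structure)."""
    payload = [
        {
            "name": s.name,
            "family": s.family,
            "params": list(s.params),
            "units": s.units,
            "truncation": None if s.truncation is None else list(s.truncation),
        }
        for s in registry
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_registry(path) -> list[AssumptionSpec]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [
        AssumptionSpec(
            name=item["name"],
            family=item["family"],
            params=tuple(item["params"]),
            units=item.get("units", ""),
            truncation=None if item.get("truncation") is None else tuple(item["truncation"]),
        )
        for item in payload
    ]
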