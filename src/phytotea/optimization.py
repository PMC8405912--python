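"""Optimization of the CEX column diameter under uncertainty.

The retrofitting case keeps the base facility sizing fixed and treats the
cation-exchange column diameter as the single decision variable.  The
optimizer is a grid search with common random numbers: every candidate
diameter is evaluated on the *same* sampled trial inputs, so candidate
differences reflect the decision alone, not sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .assumptions import AssumptionSpec, CorrelationSpec, TrialInputMatrix, sample_trials
from .monte_carlo import SimulationPlan, run_simulation
from .tea_surrogate import EconomicsConfig, EquipmentSpec, ProcessConfig

__all__ = ["DecisionSpec", "OptimizationResult", "optimize_decision"]


@dataclass(frozen=True)
class DecisionSpec:
    """A scalar decision variable with a candidate grid and an objective."""

    name: str = "cex_column_diameter"
    candidates: tuple = (0.5, 0.75, 1.0, 1.25, 1.5, 2.0)  # m
    objective: str = "irr_after_tax"
    statistic: str = "mean"  # mean | median | quantile
    quantile: float = 0.5
    direction: str = "max"  # max | min

    def __post_init__(self) -> None:
        cands = tuple(float(c) for c in self.candidates)
        if not cands or any(c <= 0 for c in cands):
            raise ValueError("candidate grid must be non-empty and positive")
        object.__setattr__(self, "candidates", cands)
        if self.statistic not in ("mean", "median", "quantile"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.direction not in ("max", "min"):
            raise ValueError("direction must be 'max' or 'min'")


@dataclass(frozen=True)
class OptimizationResult:
    """Per-candidate objective estimates and the selected candidate."""

    table: pd.DataFrame  # candidate, estimate, se, n
    selected: float
    seed: int
    failures: tuple = ()

    def __post_init__(self) -> None:
        if self.selected not in set(self.table["candidate"]):
            raise ValueError("selected candidate not in the evaluated grid")


def _statistic(values: np.ndarray, spec: DecisionSpec) -> tuple[float, float]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return float("nan"), float("nan")
    if spec.statistic == "mean":
        return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))
    if spec.statistic == "median":
        return float(np.median(v)), float("nan")
    return float(np.quantile(v, spec.quantile)), float("nan")


def optimize_decision(
    spec: DecisionSpec,
    plan: SimulationPlan,
    registry: Sequence[AssumptionSpec],
    correlation: Optional[CorrelationSpec] = None,
    equipment: EquipmentSpec = EquipmentSpec(),
    process_config: ProcessConfig = ProcessConfig(),
    econ_config: EconomicsConfig = EconomicsConfig(),
    evaluator: Optional[Callable[[TrialInputMatrix, EquipmentSpec], np.ndarray]] = None,
) -> OptimizationResult:
    """Grid search over the decision variable with common random numbers.

    Trial inputs are sampled once from ``plan.seed`` and reused for every
    candidate.  By default each candidate's objective is the chosen
    statistic of the objective forecast from a full surrogate simulation at
    the plan's first selling price (profitability statistics must not mix
    prices).  A custom ``evaluator(inputs, equipment) -> per-trial values``
    may replace the surrogate, e.g. for response-surface studies.
    """
    inputs = sample_trials(registry, correlation, plan.n_trials, plan.seed)
    price = plan.prices[0]
    rows, failures = [], []
    for cand in spec.candidates:
        eq = replace(equipment, **{spec.name: cand})
        try:
            if evaluator is not None:
                values = np.asarray(evaluator(inputs, eq), dtype=float)
            else:
                records = run_simulation(
                    replace(plan, prices=(price,), scenario=f"{spec.name}={cand:g}"),
                    registry,
                    correlation,
                    eq,
                    process_config,
                    econ_config,
                    inputs=inputs,
                )
                values = records[spec.objective].to_numpy(dtype=float)
        except Exception as exc:
            failures.append((cand, repr(exc)))
            continue
        est, se = _statistic(values, spec)
        rows.append({"candidate": cand, "estimate": est, "se": se, "n": int(np.isfinite(values).sum())})

    if not rows:
        raise RuntimeError(f"all candidates failed: {failures}")
    table = pd.DataFrame(rows)
    finite = table[np.isfinite(table["estimate"])]
    if finite.empty:
        raise RuntimeError("no candidate produced a finite objective estimate")
    pick = finite["estimate"].idxmax() if spec.direction == "max" else finite["estimate"].idxmin()
    return OptimizationResult(
        table=table,
        selected=float(table.loc[pick, "candidate"]),
        seed=plan.seed,
        failures=tuple(failures),
    )
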