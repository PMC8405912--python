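"""Monte Carlo trial loop coupling the assumption sampler to the surrogate model.

The study convention: N trials per selling price with the *same* sampled
inputs reused across prices (price only enters the economics layer), so
profitability forecasts (IRR, COGS) are analyzed per price with N trials
each while process forecasts (throughput, purity) pool all N x n_prices
records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assumptions import AssumptionSpec, CorrelationSpec, TrialInputMatrix, sample_trials
from .tea_surrogate import (
    DEFAULT_SELLING_PRICES,
    EconomicsConfig,
    EquipmentSpec,
    INPUT_NAMES,
    ProcessConfig,
    ProcessInputs,
    batch_duration,
    economics,
    run_batch,
)

__all__ = [
    "SimulationPlan",
    "run_simulation",
    "split_forecasts",
    "PROFITABILITY_FORECASTS",
    "PROCESS_FORECASTS",
]

PROFITABILITY_FORECASTS = ("irr_after_tax", "cogs")
PROCESS_FORECASTS = ("annual_throughput_kg", "purity")


@dataclass(frozen=True)
class SimulationPlan:
    """How many trials, at which selling prices, under which scenario label."""

    n_trials: int
    prices: tuple = DEFAULT_SELLING_PRICES
    seed: int = 0
    scenario: str = "base"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        prices = tuple(float(p) for p in self.prices)
        if not prices or any(p <= 0 for p in prices):
            raise ValueError("need >= 1 positive selling price")
        object.__setattr__(self, "prices", prices)


def run_simulation(
    plan: SimulationPlan,
    registry: Sequence[AssumptionSpec],
    correlation: Optional[CorrelationSpec] = None,
    equipment: EquipmentSpec = EquipmentSpec(),
    process_config: ProcessConfig = ProcessConfig(),
    econ_config: EconomicsConfig = EconomicsConfig(),
    inputs: Optional[TrialInputMatrix] = None,
) -> pd.DataFrame:
    """Run the full trial loop; returns one record per (trial, price).

    Inputs are sampled once (or passed in pre-sampled, e.g. for
    common-random-number studies) and reused across prices, so process
    forecasts are price-invariant by construction.  Trials whose IRR is
    undefined (no cash-flow sign change) keep NaN in ``irr_after_tax`` with
    ``irr_defined = False``; no trial is dropped.
    """
    if inputs is None:
        inputs = sample_trials(registry, correlation, plan.n_trials, plan.seed)
    if len(inputs) != plan.n_trials:
        raise ValueError(
            f"input matrix has {len(inputs)} rows but the plan asks for {plan.n_trials}"
        )
    missing = set(INPUT_NAMES) - set(inputs.names)
    if missing:
        raise ValueError(f"input matrix missing process inputs: {sorted(missing)}")

    values = {k: inputs.data[k].to_numpy() for k in INPUT_NAMES}
    records: list[dict] = []
    for i in range(plan.n_trials):
        trial_inputs = ProcessInputs(**{k: float(values[k][i]) for k in INPUT_NAMES})
        batch = run_batch(trial_inputs, equipment, process_config)
        duration = batch_duration(trial_inputs, equipment, process_config, batch=batch)
        base = {
            "scenario": plan.scenario,
            "trial": i,
            **{k: float(values[k][i]) for k in INPUT_NAMES},
            "annual_throughput_kg": None,
            "purity": batch.purity,
            "n_clamp_events": len(batch.clamp_events),
        }
        for price in plan.prices:
            econ = economics(
                batch,
                duration,
                price,
                econ_config,
                equipment,
                growth_time=trial_inputs.field_growth_time,
            )
            rec = dict(base)
            rec.update(
                price=price,
                irr_after_tax=econ.irr_after_tax,
                irr_defined=econ.irr_defined,
                cogs=econ.cogs,
                annual_throughput_kg=econ.annual_throughput_kg,
                n_batches_per_year=econ.n_batches_per_year,
            )
            records.append(rec)

    df = pd.DataFrame.from_records(records)
    order = (
        ["scenario", "price", "trial"]
        + list(INPUT_NAMES)
        + [
            "irr_after_tax",
            "irr_defined",
            "cogs",
            "annual_throughput_kg",
            "purity",
            "n_batches_per_year",
            "n_clamp_events",
        ]
    )
    return df[order]


def split_forecasts(records: pd.DataFrame) -> tuple[dict, pd.DataFrame]:
    """Split trial records into per-price profitability tables and a pooled process table.

    Returns ``(profitability, process)`` where ``profitability`` maps each
    selling price to its n-trial table of IRR/COGS and ``process`` pools
    throughput/purity across all prices.
    """
    if records.empty:
        raise ValueError("no trial records")
    profitability = {
        float(price): grp[["trial", *PROFITABILITY_FORECASTS, "irr_defined"]].reset_index(
            drop=True
        )
        for price, grp in records.groupby("price", sort=True)
    }
    process = records[["price", "trial", *PROCESS_FORECASTS]].reset_index(drop=True)
    return profitability, process
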