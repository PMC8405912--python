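"""Which inputs drive the forecasts: tornado sweep and contribution to variance.

The tornado sweep moves one assumption at a time to its 10th/90th
percentile with the others at base; contribution to variance attributes
forecast variance via signed, normalized squared Spearman correlations
over a Monte Carlo run.
"""

from phytotea import (
    SimulationPlan,
    cost_breakdown_at,
    contribution_to_variance,
    default_registry,
    run_simulation,
    tornado,
)
from phytotea.tea_surrogate import INPUT_NAMES, ProcessInputs
from phytotea.uq_analysis import assumption_quantile

registry = default_registry()
base = {s.name: assumption_quantile(s, 0.5) for s in registry}


def irr_model(inputs: dict) -> float:
    res = cost_breakdown_at(ProcessInputs(**inputs), price=6.0)
    return res.irr_after_tax

torn = tornado(irr_model, base, registry, percentiles=(0.10, 0.90))
print("tornado on IRR after tax (6 $/g), largest swings first:")
for row in torn.table.itertuples(index=False):
    print(f"  {row.parameter:20s} low {row.low:8.3f}  high {row.high:8.3f}  "
          f"swing {row.swing:.3f}")

records = run_simulation(SimulationPlan(n_trials=4000, prices=(6.0,), seed=42), registry)
ctv = contribution_to_variance(records[list(INPUT_NAMES)], records["irr_after_tax"])
print("\ncontribution to IRR variance (signed %):")
for name, share in ctv.shares.items():
    print(f"  {name:20s} {share:+7.1f}%")
print("shares are signed by correlation direction; absolute values sum to 100%")
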