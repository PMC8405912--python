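"""Retrofit sizing of the cation-exchange column under uncertainty.

Grid search over candidate CEX column diameters with common random
numbers: every candidate sees the same sampled inputs, so differences in
mean IRR reflect the sizing decision alone.  A bigger column raises the
product-mass cap (fewer clamps) but costs more capital.
"""

from phytotea import DecisionSpec, SimulationPlan, default_registry, optimize_decision

spec = DecisionSpec(candidates=(0.5, 0.75, 1.0, 1.25, 1.5, 2.0))
plan = SimulationPlan(n_trials=1500, prices=(6.0,), seed=42)
res = optimize_decision(spec, plan, default_registry())

print("candidate diameter (m) -> mean IRR after tax +/- SE:")
for row in res.table.itertuples(index=False):
    marker = "  <-- selected" if row.candidate == res.selected else ""
    print(f"  {row.candidate:5.2f}  {row.estimate:8.2%} +/- {row.se:.2%}  (n={row.n}){marker}")
print(f"\nselected diameter: {res.selected} m (maximizes estimated mean IRR)")
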