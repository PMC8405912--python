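"""Fit the temperature-dependent growth model to synthetic chamber data.

Generates ten two-temperature chamber regimes with 0.5 g/plant dry-weight
noise, fits (A, k, S, H) by pooled-RMSE minimization, and compares the
fitted rate curve with the generating truth.
"""

import numpy as np

from phytotea import (
    GrowthModelParams,
    SYNTHETIC_TRUE_PARAMS,
    SyntheticExperimentDesign,
    fit_growth_params,
    growth_rate,
    synth_chamber_data,
)

design = SyntheticExperimentDesign(noise_sd=0.5, seed=42)
chambers = synth_chamber_data(design)
print(f"{len(chambers)} chamber regimes, {sum(len(d.days) for d in chambers)} observations")

truth = SYNTHETIC_TRUE_PARAMS
init = GrowthModelParams(A=truth.A * 1.1, k=truth.k * 0.9, S=truth.S * 1.1, H=truth.H * 0.9)
fit = fit_growth_params(chambers, init=init)

print(f"fitted params: A={fit.params.A:.4g}  k={fit.params.k:.5g} K  "
      f"S={fit.params.S:.4g}  H={fit.params.H:.6g} K")
print(f"pooled RMSE = {fit.rmse:.3f} g/plant (noise floor ~0.5), R^2 = {fit.r2:.4f}")

T = np.linspace(288.0, 308.0, 5)
r_fit = growth_rate(T, fit.params)
r_true = growth_rate(T, truth)
print("rate curve check (day^-1):")
for t, rf, rt in zip(T, r_fit, r_true):
    print(f"  T={t:6.1f} K   fitted r={rf:.4f}   true r={rt:.4f}")
# The RMSE near the noise level and the close rate curves show the fit
# captures the temperature response; the raw parameters themselves sit on a
# shallow likelihood ridge and are less well determined than the curve.
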