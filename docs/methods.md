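# Methods

This note documents the models implemented in `phytotea`, the defaults
behind them, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Growth model

Dry weight compounds in discrete steps, `W(t+Δt) = W(t)·(1 + r(T)·Δt)`,
with the temperature response

```
r(T) = A·T·exp(−k/T) / (1 + exp(S − H/T)).
```

**Units and conventions.** `k` and `H` are printed in kelvin in the chamber
literature, so both exponents divide by `T`: `exp(−k/T)` and
`exp(S − H/T)`. Because the update multiplies `r` by the current weight,
`r` acts as a *relative* growth rate (day⁻¹), even though chamber studies
sometimes quote it in g/(plant·day); the compounding form makes the
distinction consequential and we state it explicitly.

**Integration step.** Hourly steps (`Δt = 1/24` day) when hourly
temperatures are available (field simulations); daily steps at the
hour-weighted day temperature `(h_high·T_high + h_low·T_low)/24`
(default 9 h/15 h) for chamber regimes. Hourly and daily stepping agree
only as `Δt → 0`; at `r ≈ 0.15 day⁻¹` the one-day discrepancy is ≈1% and
compounds multiplicatively over longer windows, so a single convention is
used per data source.

**Reference parameter values.** `PUBLISHED_TOBACCO_PARAMS`
(A = 924.67 day⁻¹K⁻¹, k = 1992 K, S = 5.434, H = 22780 K) reproduces the
parameter set reported for the classic chamber-grown tobacco data and is
the default initial guess. Two caveats we verified numerically and chose
to document rather than "fix": (i) with these values
`exp(S − H/T) < 10⁻26` below 320 K, so the inactivation term is inert and
r(T) is monotone increasing across the whole horticultural range — these
printed values cannot reproduce a growth optimum at 18.5–28.5 °C; (ii) the
implied rates (r ≈ 360 day⁻¹ at 300 K) are only meaningful under the
absolute-rate reading of the original source, not the relative-rate
compounding model. The synthetic generator therefore uses its own truth
(`SYNTHETIC_TRUE_PARAMS`, A = 0.45, k = 1992, S = 80, H = 24400), chosen
once so that r is horticulturally plausible (~0.15 day⁻¹ near 297 K, an
optimum near 296.5 K, decline above) and a 0.5 g seedling reaches ~20–26 g
in 27 days.

**Fitting.** `fit_growth_params` minimizes the RMSE pooled over all
observation points of all regimes with equal weight (the data source is
silent on weighting). Each regime's unobserved initial dry weight is a
conditionally linear nuisance profiled out in closed form — anchoring the
curve on the first (noisy) observation would multiply the whole trajectory
by that observation's error. The optimizer is bounded local least squares
(trust-region reflective, `A, k, H > 0`, tolerances 1e-14), deterministic
given the initial guess. Because `exp(S − H/T)` creates two degenerate
branches (saturated everywhere / negligible everywhere) with exactly flat
plateaus, the fit also builds a data-driven start: per-regime rates from
the log-linear dry-weight slope, the Arrhenius pair from the rising limb
of the rate curve, the inactivation pair from the declining limb; all
starts are polished on the pooled residuals and the best kept. If nothing
improves on the initial guess, the initial guess is returned flagged
`converged=False` — the fit never reports a worse RMSE than its start.

**Identifiability (known limitation).** Over any realistic chamber range
(≈285–310 K) `log r ≈ log A + log T − k/T − softplus(S − H/T)`, and
`softplus(S − H/T)` is locally almost linear in `1/T` — almost collinear
with `log A − k/T`. The likelihood is therefore nearly flat along the
(A, k) and (S, H) ridges: re-optimizing the other three parameters after
displacing k by 10% changes the noise-free pooled RMSE by only
~0.008 g/plant, far below realistic measurement noise. Consequently the
*rate curve* r(T) is well identified (a few % over the sampled range at
0.5 g noise) but the individual parameters are not; no estimator can pin
them at that noise level. Tests assert exact parameter recovery on
noise-free data and rate-curve recovery under noise.

## Yield distribution

Monthly yields simulate exactly 27 × 24 hourly steps from a 0.5 g/plant
seedling, starting at the first hour of the first day of each month (the
window fits inside February in any year). "Day 27 after emergence = day 42
post seeding" is bookkeeping for a 15-day germination period; the
simulation always spans 27 days. Missing weather hours are linearly
interpolated up to 3-hour gaps; longer gaps invalidate the month, which is
skipped with a logged warning.

Normalized yields (max = 1 by construction) are summarized by a
four-parameter beta. The fit anchors the maximum at 1 (the upper endpoint
is known exactly for max-normalized data), sets the minimum just below the
sample minimum (endpoint MLE of a bounded distribution is non-regular; the
1%-of-range margin keeps the likelihood finite), and estimates α, β by
maximum likelihood with the support fixed; boundary observations are
pulled half a plotting position inside. On 10⁴ draws from
Beta(2.57, 4.80) on [0.63, 1] this recovers the shapes within ~2% and the
minimum within 0.001.

## Assumption registry

Nine uncertain inputs ship as defaults. Values with a stated basis:
field growth yield Beta(2.57, 4.80) on [0.63, 1] (the scaled-beta yield
fit; mean 0.76); expression level logistic with mean 1.50 g/kg FW; UF/DF
flux triangular at base ±25%; CEX recovery uniform at base ±10%
(0.81–0.99); harvest time on 1–10 h bounds from a 1–10 km/h harvester
speed over a 10 km pass, symmetric Beta(2, 2) shapes. Working-process
placeholders (overridable via the YAML registry): field growth time
triangular (35, 42, 49) days; plate-&-frame recovery triangular
(0.90, 0.95, 1.00) and flux triangular (75, 100, 125) L/m²/h; TFF recovery
triangular (0.85, 0.90, 0.95). The logistic scale is set for a 30% CV
(scale = CV·mean·√3/π) as a stand-in for the unpublished expression
histogram fit. The expression logistic is truncated to (0.01, 6.0) g/kg so
sampled levels stay positive; `normalize_to_mean` solves the location
numerically so the *truncated* mean equals the 1.50 g/kg target (location
families shift; bounded families scale multiplicatively, carrying
truncation bounds along).

Sampling is inverse-CDF per family (truncation restricts the uniform
deviate range), bit-reproducible per seed. Correlation, when requested, is
induced by Iman–Conover rank reordering against a Gaussian copula with the
Spearman→Pearson mapping `ρ_P = 2·sin(π·ρ_S/6)`; marginals are untouched,
non-PSD targets are rejected naming the offending pairs. No default
correlations ship (the published pairings and values are not public).

## Surrogate facility model

The facility structure is this package's own parameterized design — the
original deterministic model lives in commercial simulation software — and
every constant is a config field. Defaults (chosen once for a plausible
ultra-large base case, not calibrated to any facility): 100 t FW nominal
biomass/batch, 3 L extraction buffer per kg FW, 90% clarified-volume
fraction, 10× UF/DF volume reduction, 200/100 m² membrane areas, rated
caps 250,000 L stream volume and 120 kg product through the base 1 m CEX
column. Clamping follows the fixed-sizing convention: harvested biomass is
reduced so the extraction stream fits the rated volume (field stage), and
product mass is capped at the CEX stage; the cap scales with
`oversize_factor` and with the column cross-section `(d/d_base)²`.
Purity is a fixed enrichment chain (0.05 × 1.6 × 2.5 × 4.5 = 0.90); no
purity mechanism is claimed beyond stage-wise enrichment.

Batch duration = harvest time + 24 h fixed extraction/turnaround +
filtration stage times (volume/(flux·area)) + 8 h chromatography; field
growth happens in parallel on the field and enters the economics instead,
scaling the biomass production cost with residence time. Economics:
batches/yr = ⌊7920 h / duration⌋ (330-day year); capex =
80 M$ · oversize^0.6 + 2 M$/m² CEX cross-section; opex = maintenance (8%
of capex) + labor (6 M$/yr) + utilities (0.005 $/L) + biomass
(0.10 $/kg FW) + consumables (2000 $/kg product); COGS = opex / product.
Cash flows over a 10-year horizon with straight-line depreciation, 21% tax
and no salvage give the IRR by bracketed Brent root-finding of NPV on
[−0.99, 10] (tolerance 1e-10). Cash flows with no sign change (price too
low to ever go cash-positive) leave IRR undefined: flagged, retained, and
excluded from IRR statistics. Default selling prices (4, 6, 8) $/g span
break-even to comfortably profitable at these defaults.

## Trial loop and analyses

Inputs are sampled once per scenario from a single seeded generator and
reused across selling prices — price only touches the economics layer, so
process forecasts (throughput, purity) are price-invariant by construction
and may be pooled across prices (N trials × 3 prices = 3N process rows),
while profitability forecasts are analyzed per price. Scenario comparison
uses Welch's t (the unequal-variance form, since no variance equality is
guaranteed) and the asymptotic two-sample KS test; no multiple-testing
correction is applied (raw test results are reported). QQ points use
plotting positions `(i − 0.5)/n`. Tornado defaults to the 10th/90th
assumption percentiles and the spider grid to {5%, …, 95%}, both
config-overridable, with ties in the swing ranking broken alphabetically.
Contribution to variance uses signed normalized squared Spearman
correlations; absolute shares sum to 100% by construction. Extremal-trial
lookup breaks ties toward the lowest row position.

## Optimization

Grid search over CEX column diameter with common random numbers (every
candidate evaluated on identical sampled inputs), objective = mean IRR
after tax at a single selling price (mixing prices would average across
distinct populations), direction configurable with maximize as the
default — minimizing IRR has no economic reading. Estimates carry
standard errors (σ/√n, NaN-trials excluded); the selected candidate is the
grid argmax/argmin of the estimates.

## Synthetic data

Weather = annual sinusoid (amplitude 5 K, peak mid-July) + diurnal
sinusoid (amplitude 4 K, peak 15:00) + AR(1) noise (φ = 0.8, σ = 1.5 K)
around a 297 K mean — the simplest process with the features the yield
model is sensitive to (seasonal contrast, diurnal swing, persistence). It
is not a climatological model: no humidity, fronts, or inter-annual trend,
and synthetic years are 365 days (Feb 29 skipped). Chamber data come from
the forward model at the weighted day temperature plus additive Gaussian
noise (default 0.5 g/plant, a between-plant biological-variation scale);
the ten default regimes span 13–37 °C weighted temperature, deliberately
bracketing the optimum so both limbs of the rate curve are sampled.

Passing tests on these generators show the pipeline's internal
consistency — recovery of known parameters, invariance and bookkeeping
contracts — not agreement with any real weather record, chamber study, or
commercial facility model.

## Problem sizes

Default test and example runs use 10³–2·10⁴ trials; the trial-bookkeeping
check runs the full 20,000 × 3 design (~10 s). One million draws
cross-check the closed-form beta mean. These sizes give Monte Carlo
standard errors well inside every tolerance asserted.
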