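"""From hourly weather to a field-growth-yield assumption distribution.

Three synthetic Homestead-like years of hourly temperature drive 27-day
growth simulations starting on the first of each month (36 monthly yields);
the max-normalized yields are fitted with a four-parameter beta
distribution whose mean becomes the base-case field growth yield.
"""

from phytotea import (
    SYNTHETIC_TRUE_PARAMS,
    build_yield_table,
    fit_scaled_beta,
    normalize_by_max,
    scaled_beta_mean,
    synth_weather,
    yield_summary,
)

weather = synth_weather(years=3, seed=42)
years = sorted(weather.temps.index.year.unique())
table = build_yield_table(weather, years, SYNTHETIC_TRUE_PARAMS)

summary = yield_summary(table)
print(f"{summary['n']} monthly yields over {years}")
print(f"mean {summary['mean_g']:.2f} g/plant, SD {summary['sd_g']:.2f} g/plant "
      f"({summary['rsd_percent']:.0f}% relative SD)")

norm = normalize_by_max(table)
beta = fit_scaled_beta(norm)
print(f"scaled-beta fit: alpha={beta.alpha:.2f}, beta={beta.beta:.2f}, "
      f"min={beta.minimum:.2f}, max={beta.maximum:.2f}")
print(f"distribution mean = {scaled_beta_mean(beta):.2f} "
      "(the base-case field growth yield as a fraction of the best month)")
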