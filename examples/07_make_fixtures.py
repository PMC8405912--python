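"""Write the synthetic input files other examples and external tools can read.

Emits an hourly weather CSV (3 synthetic years), a growth-chamber CSV
(10 regimes) and the default assumption-registry YAML.
"""

from phytotea import write_fixtures

paths = write_fixtures("fixtures", seed=42)
for name, path in paths.items():
    print(f"{name:9s} -> {path}")
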