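"""End-to-end run from a declarative YAML configuration.

Equivalent to `rhits run examples/config_synthetic.yaml`.  Writes cleaned
panel, cleaning reports, coefficient tables, forest-plot-ready effect
tables, missed-care totals, trend-plot data and a reproducibility manifest.
"""

from pathlib import Path

from rhits import load_config, run_pipeline

config = load_config(Path(__file__).parent / "config_synthetic.yaml")
artifacts = run_pipeline(config)

print("effect estimates (percent of baseline mean):")
print(artifacts.effects[["indicator", "effect_kind", "percent_change",
                         "ci_low", "ci_high", "p"]].round(2)
      .to_string(index=False))

print("\nmissed care:")
print(artifacts.missed_care.round(1).to_string(index=False))

print(f"\nartifacts written to {config.output_dir}/ — rerunning with the "
      "same seed reproduces every file byte for byte.")
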