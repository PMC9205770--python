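"""Generate a synthetic facility-month panel and degrade its reporting.

The generator runs the segmented impact model forward with known
parameters, so every downstream estimate can be checked against truth.
"""

from rhits import CorruptionSpec, GeneratingModel, corrupt_panel, simulate_panel

model = GeneratingModel(
    n_units=6, facilities_per_unit=10,
    beta0=120.0,      # baseline visits per facility-month
    beta1=0.5,        # secular trend per month
    beta2=-30.0,      # immediate drop when the pandemic is declared (-25%)
    beta3=2.0,        # partial within-shock recovery slope
    beta4=-8.0,       # level gap remaining in the final quarter
    season_effects={"winter": -10.0, "spring": 5.0,
                    "summer": 10.0, "fall": -5.0},
    dispersion=0.02,  # NB noise: var = mu * (1 + 0.02 * mu)
    seed=1,
)
panel = simulate_panel(model)
print(f"panel: {len(panel)} facility-month records, "
      f"{panel['facility_id'].nunique()} facilities")

spec = CorruptionSpec(dropout_rate=0.08, pandemic_dropout_multiplier=2.0,
                      outlier_rate=0.01, outlier_scale=5.0, seed=2)
corrupted, log = corrupt_panel(panel, spec, timeline=model.timeline)
print(f"after corruption: {corrupted['count'].isna().sum()} missing reports, "
      f"{(log['action'] == 'outlier').sum()} injected outliers")

by_regime = corrupted.assign(regime=corrupted["month"].map(
    model.timeline.regime)).groupby("regime")["count"].mean()
print("\nmean facility-month count by study regime:")
print(by_regime.round(1).to_string())
print("\nThe shock-window mean sits well below baseline (the injected "
      "level drop), and the resumption mean recovers most of the gap.")
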