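# Full-pipeline configuration: synthetic three-indicator study.
# All analysis defaults apply where a key is omitted: 15/24-month
# completeness, 3.5 SD outlier rule, 6-month shock window, final-quarter
# resumption, alpha 0.05.
seed: 11
output_dir: scratch/example_run
timeline: {total_months: 24, baseline_months: 15, shock_months: 6}
cleaning: {min_months_reported: 15, outlier_z: 3.5}
synthetic_models:
  - {indicator: anc, n_units: 6, facilities_per_unit: 10, beta0: 120,
     beta1: 0.5, beta2: -30, beta3: 2, beta4: -8, dispersion: 0.02}
  - {indicator: delivery, n_units: 6, facilities_per_unit: 10, beta0: 60,
     beta2: -9, beta4: -3, dispersion: 0.02}
  - {indicator: pnc, n_units: 6, facilities_per_unit: 10, beta0: 80,
     beta2: -24, beta4: -6, dispersion: 0.02}
corruption: {dropout_rate: 0.08, pandemic_dropout_multiplier: 2.0,
             outlier_rate: 0.01, outlier_scale: 5.0}
groupings:
  maternal_newborn: [anc, delivery, pnc]
denominators:
  maternal_newborn: {population: 2000000, crude_birth_rate: 28.0}
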