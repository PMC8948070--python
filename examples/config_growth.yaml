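# Analysis configuration for the tree-growth arm (Objective-1 formula).
response_metric: growth
effect_measure: smd
m_imputations: 10
master_seed: 1
fixed_effects: [months_since_removal, n_species, quality]
pooling_rule: average
exclude_imputed_rows: false
exclude_study_ids: []
alpha: 0.05
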