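# Example carbon-extrapolation scenarios.
#
# Baseline growth rates (agb_g0, Mg C/ha/yr), the pooled AGB enhancement
# (effect = 2.09) and the forest areas are published values. The climber
# biomass deduction (agb_climber) and the per-hectare cost range are
# SYNTHETIC placeholders: the real values live in the study's deposited
# additional data and are not reproduced here. Replace them with the
# deposited numbers to reproduce the published sequestration totals.
- label: production_forests
  agb_g0: 1.49
  effect: 2.09
  area_ha: 282879090
  agb_climber: 1.0          # placeholder, Mg C/ha/yr
  horizon_years: 10
  cost_per_ha_usd: 8.64
  cost_per_ha_range: [1.0, 18.0]   # placeholder range
- label: secondary_forests_gt3yr
  agb_g0: 4.49
  effect: 2.09
  area_ha: 29500000
  agb_climber: 1.0          # placeholder, Mg C/ha/yr
  horizon_years: 10
  cost_per_ha_usd: 8.64
  cost_per_ha_range: [1.0, 18.0]   # placeholder range
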