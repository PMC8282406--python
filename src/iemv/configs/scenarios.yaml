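# Valuation scenarios for the VSL transfer (all monetary values 2015 USD).
#
# primary:        income-ratio scaling with unit elasticity, ratio capped at 1
#                 (no country valued above the US base).
# sensitivity_1:  elasticity raised to 1.5 with the same base VSL and income;
#                 the ratio ceiling is configurable (default 1).
# sensitivity_2:  unit elasticity, base-to-country income ratio fixed at 160.
# sensitivity_3:  unit elasticity, base-to-country income ratio fixed at 100.
primary:
  vsl_base: 9400000.0
  i_base: 57900.0
  epsilon: 1.0
  ratio_ceiling: 1.0
sensitivity_1:
  vsl_base: 9400000.0
  i_base: 57900.0
  epsilon: 1.5
  ratio_ceiling: 1.0
sensitivity_2:
  vsl_base: 9400000.0
  i_base: 57900.0
  epsilon: 1.0
  fixed_ratio: 160.0
sensitivity_3:
  vsl_base: 9400000.0
  i_base: 57900.0
  epsilon: 1.0
  fixed_ratio: 100.0
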