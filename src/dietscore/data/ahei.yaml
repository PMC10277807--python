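# Alternative Healthy Eating Index, 9 estimable components, 0-10 each.
# The 0-90 component sum is rescaled to 0-100 (exact ratio 100/90).
# Cutpoints follow the published AHEI-2010 shapes, expressed in the
# units of the pipeline's dietary factors; they are data, not code —
# drop in a different table to change the definition.
pattern: AHEI
reference_year: 2018
rescale: [100, 90]
components:
  - {factor: fruit, direction: healthy, rule: cutpoint_linear, worst: 0.0, optimal: 300.0}   # g/day
  - {factor: vegetables, direction: healthy, rule: cutpoint_linear, worst: 0.0, optimal: 400.0}
  - {factor: whole_grains, direction: healthy, rule: cutpoint_linear, worst: 0.0, optimal: 90.0}
  - {factor: legumes_nuts, direction: healthy, rule: cutpoint_linear, worst: 0.0, optimal: 50.0}
  - {factor: ssb, direction: unhealthy, rule: cutpoint_linear, worst: 240.0, optimal: 0.0}
  - {factor: red_processed_meat, direction: unhealthy, rule: cutpoint_linear, worst: 170.0, optimal: 0.0}
  - {factor: seafood_omega3, direction: healthy, rule: cutpoint_linear, worst: 0.0, optimal: 250.0}  # mg/day
  - {factor: pufa, direction: healthy, rule: cutpoint_linear, worst: 2.0, optimal: 10.0}     # % energy
  - {factor: sodium, direction: unhealthy, rule: cutpoint_linear, worst: 4000.0, optimal: 1100.0}  # mg/day
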