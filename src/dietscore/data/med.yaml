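# Mediterranean diet score, 8 estimable components scored 0/1 against
# the sex-specific population median of the 2018 standardized intakes
# (alcohol is not estimable); total range 0-8, no rescaling.
pattern: MED
reference_year: 2018
rescale: [1, 1]
components:
  - {factor: vegetables, direction: healthy, rule: median_binary}
  - {factor: legumes_nuts, direction: healthy, rule: median_binary}
  - {factor: fruit, direction: healthy, rule: median_binary}
  - {factor: whole_grains, direction: healthy, rule: median_binary}
  - {factor: fish, direction: healthy, rule: median_binary}
  - {factor: mufa_sfa_ratio, direction: healthy, rule: median_binary}
  - {factor: red_processed_meat, direction: unhealthy, rule: median_binary}
  - {factor: dairy, direction: unhealthy, rule: median_binary}
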