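# DASH score, 8 components scored 1-5 by sex-specific population
# quintiles of the 2018 standardized intake distribution (reversed for
# unhealthy components); total range 8-40, no rescaling.
pattern: DASH
reference_year: 2018
rescale: [1, 1]
components:
  - {factor: fruit, direction: healthy, rule: quintile}
  - {factor: vegetables, direction: healthy, rule: quintile}
  - {factor: legumes_nuts, direction: healthy, rule: quintile}
  - {factor: whole_grains, direction: healthy, rule: quintile}
  - {factor: dairy, direction: healthy, rule: quintile}        # low-fat dairy proxy
  - {factor: sodium, direction: unhealthy, rule: quintile}
  - {factor: red_processed_meat, direction: unhealthy, rule: quintile}
  - {factor: ssb, direction: unhealthy, rule: quintile}
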