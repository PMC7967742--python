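# Business as usual: Markov-projected demand, calibration-era parameters.
name: S1
long_name: business as usual
demand_source: markov
demand_table: demands_hm2.csv
neighborhood:
  window: 3
  weights_table: neighborhood_weights.csv
conversion_matrix: s1s2
restricted: []
seed: 1
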