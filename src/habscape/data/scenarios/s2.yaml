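# Fast cultivated-land expansion: tabulated demand, construction weight 0.9.
name: S2
long_name: fast cultivated land expansion
demand_source: table
demand_table: demands_hm2.csv
neighborhood:
  window: 3
  weights_table: neighborhood_weights.csv
conversion_matrix: s1s2
restricted: []
seed: 2
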