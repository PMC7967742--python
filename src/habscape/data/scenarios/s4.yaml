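# Sustainable development: redline plus permanent-farmland preservation.
name: S4
long_name: sustainable development
demand_source: table
demand_table: demands_hm2.csv
neighborhood:
  window: 3
  weights_table: neighborhood_weights.csv
conversion_matrix: s3s4
restricted: [redline, farmland]
seed: 4
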