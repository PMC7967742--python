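# Ecological security: ecological redline frozen, relaxed conversion into
# water/wetland, damped cultivated expansion.
name: S3
long_name: ecological security
demand_source: table
demand_table: demands_hm2.csv
neighborhood:
  window: 3
  weights_table: neighborhood_weights.csv
conversion_matrix: s3s4
restricted: [redline]
seed: 3
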