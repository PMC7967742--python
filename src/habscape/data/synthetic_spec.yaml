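# Default synthetic landscape: a coastal-delta-like mosaic at 30 m cell
# size, a 2017-style class composition, and a persistence-dominated
# transition process for the calibration pair.
shape: [120, 120]
cell_size: 30.0
seed: 20170101
proportions:
  cultivated: 0.285
  garden: 0.005
  forest: 0.027
  grassland: 0.007
  construction: 0.157
  water: 0.225
  wetland: 0.141
  unused: 0.153
restricted_fraction: 0.05
driver_smoothing: 6.0
distance_seed_counts:
  dist_builtup: 4
  dist_town: 10
  dist_railway: 2
  dist_highway: 3
  dist_state_road: 4
  dist_provincial_road: 6
  dist_county_road: 12
  dist_river: 3
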