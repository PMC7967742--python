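scenario,cultivated,garden,forest,grassland,construction,water,wetland,unused
S1,0.5,0.1,0.2,0.1,1,0.1,0.1,0.1
S2,0.5,0.1,0.2,0.1,0.9,0.1,0.1,0.1
S3,0.2,0.1,0.3,0.1,0.9,0.2,0.2,0.1
S4,0.4,0.1,0.2,0.1,0.9,0.1,0.1,0.1
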