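scenario,cultivated,garden,forest,grassland,construction,water,wetland,unused
S1,215993,4262,22208,5487,177100,185178,115601,98814
S2,233273,4262,22208,5487,169957,181474,112133,95849
S3,220313,4262,23512,5487,159390,187215,116757,107707
S4,225065,4262,23097,5487,159390,186420,116179,104743
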