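code,name
1,cultivated
2,garden
3,forest
4,grassland
5,construction
6,water
7,wetland
8,unused
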