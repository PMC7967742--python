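from,cultivated,garden,forest,grassland,construction,water,wetland,unused
cultivated,1,0,1,0,1,1,1,0
garden,1,1,1,0,1,1,1,0
forest,1,0,1,0,1,1,1,0
grassland,1,1,1,1,1,1,1,0
construction,1,1,1,1,1,0,1,0
water,1,1,1,1,1,1,1,0
wetland,1,1,1,1,1,1,1,0
unused,1,1,1,1,1,1,1,1
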