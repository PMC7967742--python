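class,habitat,urban,rural_residential,transportation,mining,cultivated,saline_alkali
cultivated,0.4,0.5,0.6,0.2,0.5,0.3,0.8
garden,0.5,0.4,0.4,0.3,0.4,0.3,0.7
forest,0.9,0.9,0.8,0.7,0.7,0.5,0.4
grassland,0.7,0.7,0.4,0.6,0.6,0.4,0.3
construction,0,0,0,0,0,0,0
water,0.9,0.8,0.6,0.4,0.9,0.6,0.7
wetland,0.7,0.8,0.6,0.4,0.9,0.7,0.7
unused,0.1,0.6,0.6,0.3,0.2,0,0.9
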