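threat,max_distance_km,weight,decay
urban,10,1,exponential
rural_residential,5,0.7,exponential
transportation,2,0.6,linear
mining,4,0.8,exponential
cultivated,1,0.5,exponential
saline_alkali,1,0.6,exponential
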