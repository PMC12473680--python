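actual,soybean,grain_crops,buckwheat,perennial_grasses,fallow
soybean,146110,5854,304,517,4086
grain_crops,794,28652,111,346,618
buckwheat,1811,1406,8261,195,470
perennial_grasses,878,623,135,11482,3074
fallow,5538,4906,73,3589,42988
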