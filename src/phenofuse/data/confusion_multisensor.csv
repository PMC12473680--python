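actual,soybean,grain_crops,buckwheat,perennial_grasses,fallow
soybean,32137,202,11,43,161
grain_crops,100,6995,2,33,296
buckwheat,165,17,2333,22,22
perennial_grasses,64,157,6,2450,269
fallow,646,163,6,708,9222
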