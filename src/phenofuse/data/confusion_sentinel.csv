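actual,soybean,grain_crops,buckwheat,perennial_grasses,fallow
soybean,242900,2437,1286,1143,6561
grain_crops,553,55675,98,193,2761
buckwheat,1982,140,16548,210,853
perennial_grasses,2020,717,396,18211,2082
fallow,3154,1510,266,2665,77502
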