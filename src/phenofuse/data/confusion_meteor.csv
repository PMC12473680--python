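actual,soybean,grain_crops,buckwheat,perennial_grasses,fallow
soybean,33785,210,68,43,477
grain_crops,685,7611,13,205,501
buckwheat,520,398,1392,38,171
perennial_grasses,260,331,105,2956,967
fallow,1008,221,157,438,11238
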