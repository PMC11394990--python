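category,per_capita
dairy,38.76
starch,54.31
grain,77.7
meat,91.37
soy,19.35
produce,93.67
edible_oil,5.49
catering,76.53
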