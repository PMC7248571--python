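id,population,gni_total
LIC,900000000.0,700000000000.0
lower-MIC,2700000000.0,5900000000000.0
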