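COG0012
COG0016
COG0018
COG0172
COG0215
COG0495
COG0525
COG0533
COG0541
COG0552
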