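era_label,family,location,scale,lower_trunc,upper_trunc
premodern,normal,1.71,0.073,1.0,inf
modern,normal,1.0185,0.0028,1.0,inf
early_modern_C4,offset_halfnormal,1.0,0.07653061224489796,1.0,1.3
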