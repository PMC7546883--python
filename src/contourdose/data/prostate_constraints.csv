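structure,constraint_text
CTV,V40Gy ≥ 95%
Bladder,V20Gy ≤ 40%
Bladder,V40Gy ≤ 10%
Femur L,V16Gy ≤ 5%
Femur R,V16Gy ≤ 5%
Rectum,V20Gy ≤ 50%
Rectum,V32Gy ≤ 20%
Rectum,V36Gy ≤ 10%
Rectum,V40Gy ≤ 5%
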