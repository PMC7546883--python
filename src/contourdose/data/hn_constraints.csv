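structure,constraint_text
Brain,Max <60Gy
Brainstem,Max <52Gy
Chiasm,Max <52Gy
Cord,Max <45Gy
Esophagus,Mean <25Gy
Larynx,Mean <40Gy
Lips,Mean <20Gy
Mandible,V70Gy <5%
Optic nerve L,Max <52Gy
Optic nerve R,Max <52Gy
Orbit L,Mean <30Gy
Orbit R,Mean <30Gy
Parotid contralateral,Mean <26Gy
Parotid contralateral,V30Gy <50%
Pharynx,Mean <40 Gy
Pharynx,V45Gy <33%
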