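marker,tag
NFkB,M1
STAT1,M1a
STAT6,M2a
ERK,M2b
STAT3,M2c
HIF1a,M2d
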