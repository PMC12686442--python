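symbol	role	direction	weight
LAMP2	effector	1	2
HSPA8	effector	1	1
HSP90AA1	effector	1	1
DNAJB1	effector	1	1
GFAP	positive_modulator	1	1
NCOR1	positive_modulator	1	1
NFE2L2	positive_modulator	1	1
PHLPP1	positive_modulator	1	1
RARA	negative_modulator	-1	1
AKT1	negative_modulator	-1	1
RICTOR	negative_modulator	-1	1
CTSA	negative_modulator	-1	1
EEF1A1	negative_modulator	-1	1
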