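allele	2DL2 Reaction 1	2DL2 Reaction 2	2DL2 Reaction 3	2DL2 Reaction 4	2DL2 Optional 1	2DL2 Optional 2
KIR2DL2*001	1	0	0	0	0	0
KIR2DL2*00102	1	0	0	0	0	0
KIR2DL2*009	1	0	0	0	1	0
KIR2DL2*003	0	1	1	0	0	0
KIR2DL2*0030101	0	1	1	0	0	0
KIR2DL2*004	0	1	1	0	1	0
KIR2DL2*006	0	1	1	0	0	1
KIR2DL2*005	0	0	0	1	0	0
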