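allele	2DL3 Reaction 1	2DL3 Reaction 2	2DL3 Reaction 3	2DL3 Reaction 4	2DL3 Reaction 5	2DL3 Optional 1	2DL3 Optional 2	2DL3 Optional 3	2DL3 Optional 4	2DL3 Optional 5	2DL3 Optional 6
KIR2DL3*001	1	0	0	0	1	0	0	0	0	0	0
KIR2DL3*0010101	1	0	0	0	1	0	0	0	0	0	0
KIR2DL3*009	1	0	0	0	1	1	0	0	0	0	0
KIR2DL3*015	1	0	0	0	1	0	1	0	0	0	0
KIR2DL3*017	1	0	0	0	1	0	0	1	0	0	0
KIR2DL3*002	0	1	0	0	0	0	0	0	0	0	0
KIR2DL3*014	0	1	0	0	0	0	0	0	1	0	0
KIR2DL3*018	0	1	0	0	0	0	0	0	0	1	0
KIR2DL3*005	0	0	1	0	0	0	0	0	0	0	0
KIR2DL3*010	0	0	1	0	0	0	0	0	0	0	1
KIR2DL3*003	0	0	0	1	0	0	0	0	0	0	0
KIR2DL3*006	0	0	0	1	0	1	0	0	0	0	0
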