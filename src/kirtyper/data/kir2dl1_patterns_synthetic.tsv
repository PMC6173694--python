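allele	2DL1 Reaction 1	2DL1 Reaction 2	2DL1 Reaction 3	2DL1 Reaction 4	2DL1 Reaction 5	2DL1 Reaction 6	2DL1 Optional 1	2DL1 Optional 2	2DL1 Optional 3	2DL1 Optional 4	2DL1 Reaction 7 (3DP1)	2DL1 Reaction 7 (3DP1V)
KIR2DL1*001	1	0	0	0	0	0	0	0	0	0	0	0
KIR2DL1*007	1	0	0	0	0	0	0	0	0	0	0	0
KIR2DL1*006	1	0	0	0	0	0	1	0	0	0	0	0
KIR2DL1*002	0	1	0	0	0	0	0	0	0	0	0	0
KIR2DL1*009	0	1	0	0	0	0	0	0	0	0	0	0
KIR2DL1*008	0	1	0	0	0	0	0	1	0	0	0	0
KIR2DL1*003	0	0	1	0	0	0	0	0	0	0	0	0
KIR2DL1*00303	0	0	1	0	0	0	0	0	0	0	0	0
KIR2DL1*010	0	0	1	0	0	0	0	0	1	0	0	0
KIR2DL1*004	0	0	0	1	0	0	0	0	0	0	0	0
KIR2DL1*011	0	0	0	1	0	0	0	0	0	1	0	0
KIR2DL1*012	0	0	0	0	1	0	0	0	0	0	0	0
KIR2DL1*021	0	0	0	0	1	0	0	0	0	0	0	0
KIR2DL1*020	0	0	0	0	0	1	0	0	0	0	0	0
KIR3DP1	0	0	0	0	0	0	0	0	0	0	1	0
KIR3DP1V	0	0	0	0	0	0	0	0	0	0	0	1
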