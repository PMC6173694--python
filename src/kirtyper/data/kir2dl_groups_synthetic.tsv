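allele	gene	group	tested
KIR2DL1*001	KIR2DL1	G*001	1
KIR2DL1*007	KIR2DL1	G*001	0
KIR2DL1*006	KIR2DL1	G*001	1
KIR2DL1*002	KIR2DL1	G*002	1
KIR2DL1*009	KIR2DL1	G*002	1
KIR2DL1*008	KIR2DL1	G*002	1
KIR2DL1*003	KIR2DL1	G*003	1
KIR2DL1*00303	KIR2DL1	G*003	1
KIR2DL1*010	KIR2DL1	G*003	1
KIR2DL1*004	KIR2DL1	G*004	1
KIR2DL1*011	KIR2DL1	G*004	0
KIR2DL1*012	KIR2DL1	G*012	0
KIR2DL1*021	KIR2DL1	G*012	0
KIR2DL1*020	KIR2DL1	G*020	1
KIR2DL2*001	KIR2DL2	G*001	1
KIR2DL2*00102	KIR2DL2	G*001	0
KIR2DL2*009	KIR2DL2	G*001	0
KIR2DL2*003	KIR2DL2	G*003	1
KIR2DL2*0030101	KIR2DL2	G*003	1
KIR2DL2*004	KIR2DL2	G*003	0
KIR2DL2*006	KIR2DL2	G*003	0
KIR2DL2*005	KIR2DL2	G*005	1
KIR2DL3*001	KIR2DL3	G*001	1
KIR2DL3*0010101	KIR2DL3	G*001	1
KIR2DL3*009	KIR2DL3	G*001	0
KIR2DL3*015	KIR2DL3	G*001	0
KIR2DL3*017	KIR2DL3	G*001	0
KIR2DL3*002	KIR2DL3	G*002	1
KIR2DL3*014	KIR2DL3	G*002	0
KIR2DL3*018	KIR2DL3	G*002	0
KIR2DL3*005	KIR2DL3	G*005	1
KIR2DL3*010	KIR2DL3	G*005	0
KIR2DL3*003	KIR2DL3	G*003	1
KIR2DL3*006	KIR2DL3	G*003	1
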