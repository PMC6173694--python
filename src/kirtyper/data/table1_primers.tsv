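reaction_id	gene	primer_name	role	target_position	reference_id	sequence	amplicon_bp	includes_control	position_offset
Control	APC	ControlF	forward	NA	NA	CCAAGCCCAACCTTAAGAAGAAAATTGGAG	813	1	0
Control	APC	ControlR	reverse	NA	NA	CCAAACCCACGGTACGCATGGGAACACTGC	813	1	0
2DL1 Reaction 1	KIR2DL1	2DL1R1F	forward	3680	KIR00005	AGAGATAAGACACCAGGAAGGGGAAGCCCG	388	1	0
2DL1 Reaction 1	KIR2DL1	2DL1R1R	reverse	4011	KIR00005	TGTCCAGAGGGTCACTGGGAGCTGACTC	388	1	0
2DL1 Reaction 2	KIR2DL1	2DL1R2F	forward	5499	KIR00005	GAGAGAGAGAGAGAGAGAGCATTAGGTCATAGTA	383	1	0
2DL1 Reaction 2	KIR2DL1	2DL1R2R	reverse	5820	KIR00005	TGACTTTGACCACTCGTATGGAGAGTCTT	383	1	0
2DL1 Reaction 3	KIR2DL1	2DL1R3F	forward	13420	KIR00005	ATCCTCTTCATCCTCCTCTTCTTTCTCCTTCACT	252	1	0
2DL1 Reaction 3	KIR2DL1	2DL1R3R	reverse	13609	KIR00005	CAGTTCAGAATCAGGCAACGGTCTGTGAAT	252	1	0
2DL1 Reaction 4	KIR2DL1	2DL1R4F	forward	5499	KIR00005	GAGAGAGAGAGAGAGAGAGCATTAGGTCATAGGA	297	1	0
2DL1 Reaction 4	KIR2DL1	2DL1R4R	reverse	5735	KIR00005	TGGCCTGGAATGTTCCGTTGACCTTGCT	297	1	0
2DL1 Reaction 5	KIR2DL1	2DL1R5F	forward	3790	KIR00005	AACCTTCCCTCCTGGCCCACCCAGGTAC	278	1	0
2DL1 Reaction 5	KIR2DL1	2DL1R5R	reverse	4011	KIR00005	GATGTCCAGAGGGTCACTGGGAGCTGACGC	278	1	0
2DL1 Reaction 6	KIR2DL1	2DL1R6F	forward	5616	KIR00005	ATATGAGAAACCTTCTCTCTCAGCCCAGTT	202	1	0
2DL1 Reaction 6	KIR2DL1	2DL1R6R	reverse	5761	KIR00005	GTGGGTGGCAGGGCCCAGAGGAAAGTAA	202	1	0
2DL1 Reaction 7 (3DP1)	KIR3DP1	3DP1F	forward	NA	NA	ACGTGTTGTGAGTTGGTCATAGTGA	649	0	0
2DL1 Reaction 7 (3DP1)	KIR3DP1	3DP1R	reverse	NA	NA	GCCCTCTGACCTGTGACCATGATC	649	0	0
2DL1 Reaction 7 (3DP1V)	KIR3DP1	3DP1VF	forward	NA	NA	AAGTGGAAATGGGAGAATCTTCTGAC	382	0	0
2DL1 Reaction 7 (3DP1V)	KIR3DP1	3DP1R	reverse	NA	NA	GCCCTCTGACCTGTGACCATGATC	382	0	0
2DL1 Optional 1	KIR2DL1	2DL1O1F	forward	71	KIR00005	GTTGGTCATAGTGAAGGACACTAGGTGTCAAATTCTATC	274	1	0
2DL1 Optional 1	KIR2DL1	2DL1O1R	reverse	281	KIR00005	TCACCAACACACGCCATGCTGACGTC	274	1	0
2DL1 Optional 2	KIR2DL1	2DL1O2F	forward	281	KIR00005	CTCCGGCAGCACCATGTCGCTCTTAT	390	1	0
2DL1 Optional 2	KIR2DL1	2DL1O2R	reverse	620	KIR00005	CCGTAACTCCACCTCCAGGCCCATTA	390	1	0
2DL1 Optional 3	KIR2DL1	2DL1O3F	forward	3787	KIR00005	AAACCTTCCCTCCTGGCCCACCCAAA	376	1	0
2DL1 Optional 3	KIR2DL1	2DL1O3R	reverse	4110	KIR00005	CTTCCTTACAGCCACCTGGGTCTCCAGT	376	1	0
2DL1 Optional 4	KIR2DL1	2DL1O4F	forward	3942	KIR00005	GGGTCTCCAAGGCCAACTTCTCCATGG	222	1	0
2DL1 Optional 4	KIR2DL1	2DL1O4R	reverse	4110	KIR00005	CTTCCTTACAGCCACCTGGGTCTCCACT	222	1	0
2DL2 Reaction 1	KIR2DL2	2DL2R1F	forward	5663	KIR00012	TATCCAGGGAGGGGGAGGCCCATGATT	211	1	0
2DL2 Reaction 1	KIR2DL2	2DL2R1R	reverse	5820	KIR00012	TGAGACAGATATGGGGTTTCCTCACCAG	211	1	0
2DL2 Reaction 2	KIR2DL2	2DL2R2F	forward	5663	KIR00012	TATCCAGGGAGGGGGAGGCCCATGATT	210	1	0
2DL2 Reaction 2	KIR2DL2	2DL2R2R	reverse	5820	KIR00012	GAGACAGATATGGGGTTTCCTCACCCA	210	1	0
2DL2 Reaction 3	KIR2DL2	2DL2R3F	forward	13995	KIR00012	ACAGATGCTGCGGTAATGGACCAAGATT	309	1	0
2DL2 Reaction 3	KIR2DL2	2DL2R3R	reverse	14249	KIR00012	ATCTGGACTCAGCATTTGGAAGTTCCCC	309	1	0
2DL2 Reaction 4	KIR2DL2	2DL2R4F	forward	11984	KIR00012	CTACTTCCAATCACCTGTGGAGATTCATG	2322	0	-1
2DL2 Reaction 4	KIR2DL2	2DL2R4R	reverse	14249	KIR00012	ATCTGGACTCAGCATTTGGAAGTTCCTT	2322	0	0
2DL2 Optional 1	KIR2DL2	2DL2O1F	forward	3754	KIR00012	AACCTTCCCTCCTGGCCCACCCAGGTTC	191	1	0
2DL2 Optional 1	KIR2DL2	2DL2O1R	reverse	3890	KIR00012	CATCATGGGACCGATGGAGAAGTTGGTT	191	1	0
2DL2 Optional 2	KIR2DL2	2DL2O2F	forward	3754	KIR00012	AACCTTCCCTCCTGGCCCACCCAGGTAG	191	1	0
2DL2 Optional 2	KIR2DL2	2DL2O2R	reverse	3890	KIR00012	CATCATGGGACCGATGGAGAAGTTGGGT	191	1	0
2DL3 Reaction 1	KIR2DL3	2DL3R1F	forward	13892	KIR00014	ATGAAATGAGGGCCCAGAAGTGCCCTGT	314	1	0
2DL3 Reaction 1	KIR2DL3	2DL3R1R	reverse	14154	KIR00014	GGTGTCTTGGGCCTCTGAGAAGGAC	314	1	0
2DL3 Reaction 2	KIR2DL3	2DL3R2F	forward	3825	KIR00014	CACAGAGAAGGGAAGTTTAAGGACACTTTGTG	399	1	0
2DL3 Reaction 2	KIR2DL3	2DL3R2R	reverse	4168	KIR00014	TGTATGGCCCCTGTGTCTGTCCTTT	399	1	0
2DL3 Reaction 3	KIR2DL3	2DL3R3F	forward	9063	KIR00014	CTGTCTCATGTTCTAGGAAACCCTTCAAATAGTTGGGT	319	1	0
2DL3 Reaction 3	KIR2DL3	2DL3R3R	reverse	9303	KIR00014	GAAGGATGTCAGATTGGCAATCATTCTTCTAGCTTGTAGGAAA	319	1	-1
2DL3 Reaction 4	KIR2DL3	2DL3R4F	forward	13973	KIR00014	GCCTGCAGGGAACAGAACAGTGAACAAG	233	1	0
2DL3 Reaction 4	KIR2DL3	2DL3R4R	reverse	14154	KIR00014	GGTGTCTTGGGCCTCTGAGAAGGCT	233	1	0
2DL3 Reaction 5	KIR2DL3	2DL3R5F	forward	3853	KIR00014	CCTCATTGGAGAGCACCATGATGGGGCT	430	1	0
2DL3 Reaction 5	KIR2DL3	2DL3R5R	reverse	4222	KIR00014	CCTCTCTCTGGGACATGTCTGTCTGTCTGTCTGT	430	1	0
2DL3 Optional 1	KIR2DL3	2DL3O1F	forward	3708	KIR00014	TAGGAGTCCACAGAAAACCTTCCCTCGG	323	1	0
2DL3 Optional 1	KIR2DL3	2DL3O1R	reverse	3976	KIR00014	GAATGTCCGGACACTCTCACCTGTGACG	323	1	0
2DL3 Optional 2	KIR2DL3	2DL3O2F	forward	16795	KIR00014	CCCTCCATCTGGGTGCTTGTCCTAAAGGCG	213	1	0
2DL3 Optional 2	KIR2DL3	2DL3O2R	reverse	16949	KIR00014	GCGATGAAGGAGAAAGAAGAGGAGGAGGTC	213	1	0
2DL3 Optional 3	KIR2DL3	2DL3O3F	forward	17646	KIR00014	TGAACAAGACCCTCAGGAGGTGACATTT	169	1	0
2DL3 Optional 3	KIR2DL3	2DL3O3R	reverse	17761	KIR00014	TCATGGGCAGGAGACAACTTTGGATAT	169	1	0
2DL3 Optional 4	KIR2DL3	2DL3O4F	forward	7315	KIR00014	TCCTGCAATGTTGGTCAGATGTCAGGTTCG	643	1	0
2DL3 Optional 4	KIR2DL3	2DL3O4R	reverse	7903	KIR00014	AGGCCACAGGGCCCAACTCAGGTCGT	643	1	0
2DL3 Optional 5	KIR2DL3	2DL3O5F	forward	13892	KIR00014	ATGAAATGAGGGCCCAGAAGTGCCCTGT	278	1	0
2DL3 Optional 5	KIR2DL3	2DL3O5R	reverse	14111	KIR00014	CTCTGTGTGAAAACGCAGTGATTCAACTGTTT	278	1	0
2DL3 Optional 6	KIR2DL3	2DL3O6F	forward	13892	KIR00014	ATGAAATGAGGGCCCAGAAGTGCCCTGT	278	1	0
2DL3 Optional 6	KIR2DL3	2DL3O6R	reverse	14111	KIR00014	CTCTGTGTGAAAACGCAGTGATTCAACTGTTC	278	1	0
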