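id	peptide	gene	mean_tpm	tissues_with_protein	denominator
1	AFAPFPTQF	CXorf49B	0.01	0	56
1	AFAPFPTQF	CXorf49	0.01	0	56
1	AFAPFPTQF	RP11-402P6.15	0.10	0	56
2	DYIHFVHHF	RP11-325B23.2	0.00	0	56
3	EALSASQALYTR	HIST1H4L	0.04	43	56
4	ELIKAFSK	GNGT1	0.05	1	56
5	ESAGLFQVPR	SUN3	0.13	3	56
6	EVEKILIQY	KCNU1	0.05	0	56
7	EVPGAQGQQGPR	CTAG2	0.15	0	56
7	EVPGAQGQQGPR	CTAG1B	0.03	0	56
7	EVPGAQGQQGPR	CTAG1A	0.06	0	56
8	FPVDVDHAVL	CTAG2	0.15	0	56
8	FPVDVDHAVL	CTAG1B	0.03	0	56
8	FPVDVDHAVL	CTAG1A	0.06	0	56
9	ILSDNIRNL	C1orf94	0.14	0	56
10	IPKDKSKNK	C2orf83	0.02	0	56
11	KLLELIKAFSK	GNGT1	0.05	1	56
12	KNNIYAFKI	RP11-231I13.2	0.01	0	56
13	KTLHLTIVK	C12orf50	0.07	0	56
14	KYLSRFRPK	TRPC5	0.08	0	56
15	MVRSPEEGSLR	TEX19	0.13	0	56
16	MVRSVSAAAR	HIST1H2BB	0.26	44	56
17	MVRSVSAAARR	HIST1H2BB	0.26	44	56
18	REEAPRGVRM	CTAG2	0.15	0	56
18	REEAPRGVRM	CTAG1B	0.03	0	56
18	REEAPRGVRM	CTAG1A	0.06	0	56
19	SAGLFQVPR	SUN3	0.13	3	56
20	SQVHKFFLL	OR9Q1	0.04	0	56
21	SYGIYIYTY	SLC15A5	0.06	0	56
22	TVSHQIIFY	EXD1	0.06	0	56
23	VIQKVILVV	MGAT4D	0.03	0	56
24	YYFILEHAKY	SOX30	0.29	0	56
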