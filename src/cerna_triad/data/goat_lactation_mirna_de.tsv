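feature_id	foldChange	log2FoldChange	pval	padj	up_down	sequence
chi-miR-491-3p	5.01	2.33	0.046	0.769	Up	CTTATGCAAGATTCCCTTCTAC
chi-miR-200c	2.14	1.10	0.006	0.559	Up	TAATACTGCCGGGTAATGATGGA
chi-miR-30f-5p	2.08	1.05	0.016	0.559	Up	TGTAAACACCCTACACTCTCAGC
chi-miR-200b	2.06	1.04	0.013	0.559	Up	TAATACTGCCTGGTAATGATGA
chi-miR-378-5p	2.01	1.01	0.032	0.671	Up	CTCCTGACTCCAGGTCCTGTGT
chi-miR-22-3p	1.98	0.99	0.033	0.671	Up	AAGCTGCCAGTTGAAGAAC
chi-miR-3431-5p	1.96	0.97	0.035	0.691	Up	CCTCAGTCAGCCTTGTGGATGT
chi-miR-107-3p	1.83	0.87	0.047	0.769	Up	AGCAGCATTGTACAGGGCTAT
chi-miR-103-3p	1.78	0.83	0.043	0.769	Up	AGCAGCATTGTACAGGGCTATGA
chi-miR-204-5p	0.50	-1.00	0.020	0.559	Down	TTCCCTTTGTCATCCTATGCCT
chi-miR-301a-3p	0.48	-1.05	0.011	0.559	Down	CAGTGCAATAGTATTGTCAAAGC
chi-miR-432-5p	0.48	-1.07	0.019	0.559	Down	TCTTGGAGTAGGTCATTGGGTGG
chi-miR-454-3p	0.44	-1.19	0.011	0.559	Down	TAGTGCAATATTGCTTATAGGGT
chi-miR-502b-3p	0.44	-1.19	0.031	0.671	Down	ATCCACCTGGGCAAGGATTCTGAA
chi-miR-376a	0.44	-1.20	0.011	0.559	Down	GTAGATTCTCCTTCTATGAGT
chi-miR-542-5p	0.43	-1.22	0.012	0.559	Down	TCGGGGATCATCATGTCACGAGA
chi-miR-301b	0.42	-1.25	0.018	0.559	Down	CAGTGCAATGATATTGTCAAAGC
chi-miR-130b-5p	0.41	-1.30	0.024	0.621	Down	ACTCTTTCCCTGTTGCACTACT
chi-miR-223-5p	0.35	-1.50	0.007	0.559	Down	TGTGTATTTGACAAGCTGAGTTG
chi-miR-412-5p	0.33	-1.62	0.001	0.276	Down	TGGTCGACCAGTTGGAAAGTAAT
chi-miR-665	0.32	-1.65	0.019	0.559	Down	ACCAGTAGGCCGAGGCCCCT
chi-miR-223-3p	0.26	-1.92	0.003	0.511	Down	TGTCAGTTTGTCAAATACCCCA
chi-miR-496-3p	0.20	-2.29	0.030	0.671	Down	TGAGTATTACATGGCCAATCT
chi-miR-106a-3p	0.11	-3.18	0.047	0.769	Down	TACTGCAATGCAAGCACTTCTT
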