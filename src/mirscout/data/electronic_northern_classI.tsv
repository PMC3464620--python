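id	mirna	mirna_star	biotic_CT	biotic_AA	drought_T0h	drought_T24h	drought_S0h	drought_S24h	salt_0h	salt_1h	salt_6h	salt_24h
Seq07	AAAACGTCTTATAATTTGGAG	CAAATTATAAGATGTTTTGGC	18.06	23.17	-	-	-	-	-	-	-	-
Seq15	AAAATTATCGTAAATAGAGGTGGC	TAGCCACTTTGAGTTACGATAATT	-	8.77	2.78	6.89	4.02	7.60	-	-	-	-
Seq42	AAAGTTGTGTATCTAGAAAAG	TGGCTTTTCTAGATACATAGC	67.25	37.58	-	-	-	-	2.08	-	-	-
Seq143	AATTCGTCGAACAGCTGCAGC	ACGCGAGCTGTTTGGCGAATT	295.17	1436.67	-	-	-	-	-	-	-	-
Seq151	ACAAGTTTCGTGATTTTTGGA	CGAAAATCACGAAACTTGTCG	23.04	12.53	-	-	-	-	-	-	1.24	1.12
Seq155	ACACATGTGGATTGAGATGAATAC	TTCACATCAATCCACATATGTTGG	15.57	27.56	-	-	-	-	-	-	-	-
Seq171	ACTATGTATCTAGAAAAGCTA	TTTCTAGGTACATAGCTTTTG	-	-	2.47	1.80	1.72	-	-	-	-	0.80
Seq183	ACTTACAGTTTGGAACGGAGG	TCTGTTCCAAATTGTAAGTCG	-	5.64	-	-	-	-	-	-	-	-
Seq253	AGTCCCGAAACCTTAGTCCCGGCT	GAACCGGGACTAAAGGTGGGACAT	21.80	6.26	-	-	-	-	-	6.22	-	5.93
Seq313	ATGCCTTATAATTTGGGATGGAGA	CTCCATCCTAAATTATAAGACATT	-	-	-	-	-	-	-	-	0.77	-
Seq345	ATTTGACTGACACGGATTCTAGGA	TAGAGTTGTCCTAAGTCAAACTTT	3.74	-	-	-	-	-	-	-	-	-
Seq375	CCGGGGCCAGATCTCAGAAGC	TTCTGACTTCTGGCCCCTGCT	-	-	-	-	-	-	-	-	-	2.24
Seq376	CCTGTTTGGATCAGCCAAGGC	CTAGCTGATCCAAACAGGCCC	13.08	9.39	-	-	-	-	-	-	-	-
Seq393	CTAGCATGTTCCTCCTAAGAG	TTCTTGGGAGGAGCATGCTAG	-	5.01	-	-	-	-	-	-	-	-
Seq394	CTCCGTCCTAATATATAAGGC	CTTATATACTAGGACGGAGGG	4.36	-	-	-	-	-	-	-	-	-
Seq409	GAAACGAATCTTTTAAGTCTAATT	AACTAGACTCAAAAGATTCATCTC	3.11	-	-	-	-	-	-	-	-	-
Seq468	GATTAGTCACGATTAGTCGTCCGA	AGATCGGACGACTAATCGCGATTA	-	-	-	-	-	-	-	-	0.77	-
Seq488	GCGTGCAAGGAGCCAAGCATG	TGCCTGGCTCCCTGTATGCCA	-	-	572.49	482.28	497.41	570.24	-	-	-	-
Seq501	GGCATGGGAACATGTAGGAAGG	TTCCTGATGCCTCCCATGCCTA	11.21	-	-	-	-	-	-	-	-	-
Seq504	GGGAGCAATTCGTCGAACAGC	AGCTGTTCGACGAATGCCTCC	123.30	-	-	-	-	-	-	-	-	-
Seq509	GGGCCCAAATAGCAAGTGTTGTGA	CTCACAACACTTGCTATTTGGG	-	-	-	-	-	-	1.48	-	2.01	0.96
Seq511	GGGCGGTCACCTTGGCTAGC	TAGCCAAGGATGACTTGCCT	132.64	-	-	-	-	-	-	-	26.48	-
Seq513	GGGGGCGGACTGGGAACACAT	TGTGTTCTCAGGTCGCCCCCG	-	-	-	-	-	-	-	3404.36	-	-
Seq536	GTGCGGTTCTCCTCTGGCATG	TGCCAAAGGAGAATTGCCCTG	-	-	-	-	-	-	1.93	-	-	-
Seq538	GTGGCAGTAGAATTAATGAAGGGA	TTCTATCTCTATTAATTGTGTTGC	-	12.53	-	-	-	-	-	1.62	-	-
Seq565	GTTTTTCTCGCCGGGTGAGAAGGC	ATTCTCACTTGGGCGACGGAAAGG	-	3.13	-	-	-	-	-	-	-	-
Seq568	TAACAAGTTTAGGGATCTAGA	TTTTGGGTCCCTAAACTTGTT	-	-	2.47	3.30	-	-	-	-	-	0.80
Seq587	TAGCATGTTCCTCCTAAGAGC	TTCTTGGGAGGAGCATGCTAG	18.68	-	-	-	-	-	-	-	-	-
Seq594	TATCTAGAAAAGCTAAAACGT	GATGTTTTGGGTTTTCTAGAT	-	-	-	-	-	-	0.74	-	-	-
Seq598	TATTTGTGGACTCATGGACAT	GTCCGTGAGTCCACAAATAGG	3.11	3.13	-	-	-	-	1.78	-	2.48	1.76
Seq610	TCCATTCCAAATTGTAAGATG	GTCTTATAATTTGGAATGGAG	30.51	6.89	-	-	-	-	-	-	-	-
Seq648	TGGATGTACCAAAAAAGTCAAAGC	GTCGCTTTGACTTTTTTGGTACAT	-	-	-	-	-	-	-	3.24	-	-
Seq656	TGGGCGGTCACCTTGGCTAGC	TAGCCAAGGATGACTTGCCTA	-	65.13	27.51	38.64	72.99	62.81	-	-	-	-
Seq670	TGTTGAGGCTGGAGCGAAACTCGG	CAAGTTTGGTTTTGGTAATTAATG	-	12.53	-	-	-	-	-	-	-	-
Seq678	TTAGCGTCAAGAGACGAACACACT	AAGTGTGTTCCTCTATTTGACGCT	-	3.76	-	-	-	-	4.74	6.49	2.79	7.53
Seq700	TTGTGAGAGAAAAATACTGTTGGC	AACGAACAGTATTTTTCTCTTACA	-	16.28	-	-	-	-	-	-	-	-
Seq720	TTTTTGGTACATTGAATTTGC	AATTCGATGTACCAAAAAAGT	-	11.27	-	-	-	-	-	-	-	-
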