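name	accession	ssr	product_size	fw_primer	fw_tm	rv_primer	rv_tm
PPEST1	EY218895.1	(CA)15	170	AGTTCCGCCACATCCATTC	60.9	TTAGACAGCGGGAAAGAAGAAA	60.4
PPEST2	FG108562.1	(GCA)13	141	TGTCAATAGTGGCTCAATGCTC	60.3	ATTAGTCGTTTATCCTTCCCCG	60.5
PPEST3	EX474573.1	(TA)13	188	CAATTTTATGCGGTCTATGGGA	61.0	AGGTATGCAAAGTAATGGGTGG	60.1
PPEST4	FG116618.1	(TC)13	197	ACCCGACGCGAATTTACTTT	60.8	GGAGAGACAAGTTATGGGGTCA	60.4
PPEST5	FG107376.1	(TGC)13	190	GAGAGACATGGTGGATGGACTT	60.4	TGTCAATAGTGGCTCAATGCTC	60.3
PPEST6	FG108078.1	(AT)12	291	AAATCCACTATCCTCCTTTCCTC	59.0	TTTTGGGGTAAGATGGGG	58.2
PPEST7	EX473561.1	(CA)12	245	GTACCCTTTCCCTCCCTATGTC	60.1	GGGTTCACCAACATCCTCC	60.2
PPEST8	FG119248.1	(CA)12	140	CCACTGTAACTTGAGGAGGAGG	60.2	AGACTTGATGAGTGCGTCTCTG	59.7
PPEST9	FG117610.1	(CA)12	175	CGCACAAGAACAAAGTGGAAA	61.2	TCTTCTCGCTCCCTCGTTC	60.6
PPEST10	FG117371.1	(TC)12	236	ACTGAATCTTCTGCTTTCTCCATTC	61.4	TAAGGGAAGGGGCGGAAC	62.2
PPEST11	ES347986.1	(GA)11	162	GGTGGATACTTGTGACGACTGA	60.0	CCACTCAAACTAAACTGGAAAGC	59.4
PPEST12	FG113351.1	(AT)10	233	CTTTTCTGCCTTAGCTGCGTT	61.0	CGTGTCTCTTCCACCACTACAA	60.2
PPEST13	EY206382.1	(TC)10	222	AGCTGGAATCAGGAGCAAAT	58.9	CAGTATCAAGCGAAAGCCG	59.6
PPEST14	FK815057.1	(GA)9	228	ACGTGTTGTTTTCTGTGGAGTG	60.1	CTGGGTATTTTCTGCCTTGATT	59.5
PPEST15	FK812013.1	(TGA)9	157	AAGAAAGGTTTGGCTTCGTGT	60.2	AATGGTGCTTCATCTCCTCTTC	59.7
PPEST16	FK811085.1	(TCA)9	239	TTCTGTTCACACATCATTTCCC	59.8	TGTGGCTGTAATTTGACTGGAG	60.2
PPEST17	FG116712.1	(TGC)9	208	CTGTTCAGCAAAACGAGACG	59.6	TCCCAAGTACAAAGACGGAACT	60.0
PPEST18	EY216123.1	(CT)9	276	ACTTGCATACTCTTTCGCACAA	59.9	AAATTCATGGAAAACCTCCCTC	60.5
PPEST19	EY210796.1	(AC)9	211	ACCCATCACCGTCTCTGC	59.6	TTTCCCTTGAACAACAACCAC	59.9
PPEST20	EY210288.1	(TC)9	293	ACAGAAGAAACCATCCATTTGC	60.4	CCATATTCCCGATTGAGAGAGA	60.4
PPEST21	EX474074.1	(AG)9	244	GGATTAGTGTGGCTCAAGATGG	60.9	GCAGGAAAATAGCAAAAGGGAT	60.8
PPEST22	ES347170.1	(GT)9	229	ATGGGGTATTAAGGGAGAATGC	60.4	GGGACGTGTGTGAGTGAGATAG	59.6
PPEST23	FG120710.1	(GA)8	223	CTGCATTTCTAATTTCGCGG	60.7	GGAGGAAGTGGACAGTGAAAAC	60.0
PPEST24	FG118096.1	(TC)8	129	AGGCACATTTTGGTTGTCTTCT	60.0	ATTTAGGGAGTCAATAGCGCAG	59.8
PPEST25	EY218678.1	(TTTA)8	132	CCATTCACTTCAAATCCATCCT	60.2	AACTGGGTGGTTGGTTGTTTT	60.5
PPEST26	EY216313.1	(AC)8	217	GATTCCCCAGGCAAAATAAA	58.9	TAATCAATATGGTGGGTTCCG	59.5
PPEST27	EY213284.1	(TAAA)8	150	TTGCTAAAGACAAGCGCAACT	60.2	CCATTCACTTCAAATCCATCCT	60.2
PPEST28	EY209870.1	(CAA)8	245	GATCAAGGCGGTTAATTTCAAG	60.0	ACAATCCAGAAGGACGATGC	60.1
PPEST29	FK814636.1	(GGT)6	228	TTTGTGGAGTTCGATGACTACG	60.2	GGACACATTCCTGTTCCAATTC	60.6
PPEST30	EY218675.1	(CT)9	373	TTCGCTCTTTCTCTCTCTCTCC	59.5	ATTCTGTACGTTACCTGCCCTG	60.4
PPEST31	EY215872.1	(TA)11	400	AAACGTGCATTCTCTGCCTAAT	60.2	CTCGATATTTATTTCCCCGCT	59.5
PPEST32	EY210648.1	(TTTA)6	123	ATTCACTTCAAACCCCTCCTTT	60.2	AACTGGGTGGTTGGTTGTTTT	60.5
PPEST33	FG115100.1	(GAA)15	251	ATACTCCCTCAGAACTAGCCCC	60.0	TTCGTCTTCTTCTTCTTCCTCC	59.1
PPEST34	EY215687.1	(AAAG)5	137	CACCTACAGAGATGCTGGATTG	59.8	GGGCTAAAATGTGTCTTGACTTG	60.0
PPEST35	EY214242.1	(GT)15	245	TAGTCACAACACACGAACCACA	60.1	TTAACCGTGAGAGTACCAGCAA	59.8
PPEST36	EY203279.1	(TTTA)6	123	ATTCACTTCAAACCCCTCCTTT	60.2	AACTGGGTGGTTGGTTGTTTT	60.5
PPEST37	EX474189.1	(AT)7	208	ACCGTGCAACCATTTTAAGTTC	60.3	AGTTATTCTTCTTCTTACTGCGCC	59.5
PPEST38	FK811878.1	(AG)5	256	TCCAGATACTCAAGTTCCAGCC	60.6	TATAGCGTTCAGATCCACCAGA	59.7
PPEST39	FG107375.1	(CT)6	292	CCCCAAAGAGAGTACACCAAAG	60.0	ATCAGCCAGTGTCGTATGAATG	60.0
PPEST40	FG114532.1	(AG)5	322	TCCCAAGGCTATTAAGTCTGGT	59.2	GGCTATCGTGCAATTTTCTTCT	59.8
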