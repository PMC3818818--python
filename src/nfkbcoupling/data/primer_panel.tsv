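pathway	gene	accession	amplicon_bp	fwd_primer	rev_primer
canonical	NFKBIA	NM_020529	116	CCGCAGGAGGTGCCG	ATCACTTCCATGGTCAGTGCC
canonical	CXCL2	NM_002089	100	ATTCACCTCAAGAACATCCAAAGTG	GCCCATTCTTGAGTGTGGCTAT
canonical	TNFAIP3	NM_001270508	111	GAAGCACCATGTTTGAAGGATACTG	CTCTGCGCTGGCTCGATC
canonical	IL6	NM_000600	90	CTGGATTCAATGAGGAGACTTGC	TCAAATCTGTTCTGGAGGTACTCTAGG
canonical	IL8	NM_000584	92	AAGACATACTCCAAACCTTTCCACC	CAATAATTTCTGTGTTGGCGCA
canonical	TSLP	NM_033035	91	TCTTGTAGCAATCGGCCACA	ACATTTCTTTGGCGAGCGA
canonical	TRAF1	NM_005658	91	TGGAAGATCACCAATGTCACCA	ATACTTGGCAGTGTAGAAGGCTGG
canonical	TRAF3	NM_145752	91	GAAGGCGTGTAAATACCGGG	ACAGTCGGTGTCTTCGTGTTTCT
canonical	NFKB2	NM_001077494	96	ACATGACTGCCCAATTTAACAACC	GGAGCCGCTGCCTCTGA
canonical	IL25	NM_022789	91	CACCCAGAGTCCTGTAGGGC	GGTTCAAGTCTCTGTCCAACTCATATC
canonical	IL33	NM_033439	51	AACACCCCTCAAATGAATCAGGT	TTGGCATGCAACCAGAAGTCT
noncanonical_emt	TNIP1	NM_001252385	92	ATCCAGTGGCACCTCCTCTG	CCAGCGCCATCGCATT
noncanonical_emt	ACTA2	NM_001141945	91	TGTAAGGCCGGCTTTGCT	TTCCCACCATCACCCCCT
noncanonical_emt	COL1A1	NM_000088	95	CCAGAAGAACTGGTACATCAGCA	CGCCATACTCGAACTGGAATC
noncanonical_emt	VIM	NM_003380	91	GCTCAATGTTAAGATGGCCCTT	TGGAAGAGGCAGAGAAATCCTG
noncanonical_emt	DES	NM_001927	91	GGAGAGGAGAGCCGGATCA	GGACCTCAGAACCCCTTTGC
noncanonical_emt	TWIST1	NM_000474	101	TCTCGGTCTGGAGGATGGA	CAATGACATCTAGGTCTCCG
noncanonical_emt	TWIST2	NM_001271893	119	ACGAGCGCCTCAGCTACG	CGCGACGGACAGCCCTG
noncanonical_emt	SLUG	AF084243	91	TGTGTGGACTACCGCTGCTC	ACTCACTCGCCCCAAAGATG
noncanonical_emt	SNAI1	NM_005985	95	GCGCTCTTTCCTCGTCAGG	GGGCTGCTGGAAGGTAAACTCT
noncanonical_emt	ITGA2	NM_002203	91	AGCCGAAGTACCAACAGGAGTTATA	GCCGAGCTTCCATAAAATTGC
noncanonical_emt	S100A4	NM_002961	91	AGGGTGACAAGTTCAAGCTCAAC	GCTTCATCTGTCCTTTTCCCC
ifn	IFNB	NM_002176	95	GCAGTTCCAGAAGGAGGACG	TCCAGCCAGTGCTAGATGAATC
ifn	IFNA6	NM_021002	91	GTGGTGCTCAGCTGCAAGTC	CCAGGAGCATCATGGTCCTC
ifn	IFNA21	NM_002175	91	TGATCTGCCTCAGACCCACA	CTTCAGGCAGGAGAAAGGAGAG
ifn	CCL5	NM_002985	96	TCTACACCAGTGGCAAGTGCTC	CCCGAACCCATTTCTTCTCTG
ifn	DDX58	NM_014314	132	CCACTTAAACCCAGAGACAATAACAA	TTGCCACGTCCAGTCAATATG
ifn	LMP2	NM_002800	91	TTCACCACAGACGCTATTGCTC	CCACACCGGCAGCTGTAAT
ifn	TAP1	NM_000593	91	GTTTTTCCAACAGAACCAGACAGG	GCTCAGATTCTCACTCAGAGAATCACT
ifn	STAT1	NM_007315	104	TCCTGCTGCGGTTCAGTG	GGGTTCAACCGCATGGAAG
ifn	STAT2	NM_005419	118	CCTGAAACACAGGCTCATTGTG	TGGCACCAGCCCTAGTTCC
ifn	IRF1	NM_002198	91	AGCAAGGCCAAGAGGAAGTCA	TGCTGTGGTCATCAGGCAGA
ifn	IRF9	NM_006084	91	AGCCACAGGAAGTTACAGACACAA	GCAGTGAGTAGTCTGGCTCTGGA
ifn	SOCS3	NM_003955	91	CTTTCTGATCCGCGACAGCT	ACACTGGATGCGCAGGTTC
ifn	IFI27	NM_001130080	91	CAGTCACTGGGAGCAACTGGA	GCCCAGGATGAACTTGGTCA
ifn	MX1	NM_001144925	106	GAACCACCCATATTTCAGGGATC	ATGTGTGATGAGCTCGCTGGTA
ifn	IFNL1	NM_172140	103	AAGCCCACCACAACTGGG	ACTCTTCCAAGGCGTCCC
ifn	IFNL2	NM_172138	101	ACATGACTGGGGACTGCAC	ATCCGGGAGAGCCCCGT
ifn	IFNL3	NM_172139	99	ATGACCGGGGACTGCATG	ATCCGGGAGAGCCCCGC
growth_factor	FOS	NM_005252	91	GGGCAAGGTGGAACAGTTATCT	GTTGCGGCATTTGGCTG
growth_factor	JUN	NM_002228	91	GTCCCAGGAGCGGATCAAG	GGCGATTCTCTCCAGCTTCC
growth_factor	SOD2	NM_000636	90	TGCTTGTCCAAATCAGGATCC	TGAAGGTAGTAAGCGTGCTCCC
growth_factor	TM4SF1	NM_014220	91	GAGGTGGCCTGCTGATGCT	CCACAGTTTTCATGGCCACAG
ros_dna	NOX1	NM_007052	91	GGGCATCCCCCTGAGTCT	TCTGCTGGGAGCGGTAAAAC
ros_dna	NOX4	NM_016931	91	ACTCAACACCCTGTTGGATGACT	CCAACGGAAGGACTGGATATCT
ros_dna	HOXB9	NM_024017	91	GGCCGGATCAAACCAACC	TCCAGCGTCTGGTATTTGGTG
ros_dna	ATM	NM_000051	127	GCTTCTCAGGATAATCCGCAAG	CCAAGCAGCTTCCAACAGC
ros_dna	STK39	NM_013233	91	GCCCAAAGAGCCAAAAAGGT	CGTCGTCACTCCACTCCCA
cell_cycle	PCNA	NM_002592	91	TGCGCCGGCAATGAA	CTTTCTCCTGGTTTGGTGCTTC
cell_cycle	CDKN1A	NM_000389	92	AGCAGGCTGAAGGGTCCC	GCGTTTGGAGTGGTAGAAATCTGT
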