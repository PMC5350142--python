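# pftyper marker panel (coordinates 1-based inclusive)
marker_id	gene_label	name_fwd	seq_fwd	name_rev	seq_rev	anneal_temp	target_start	target_end	expected_len
DGPf_0	Hypothetical protein (PSF113_RS56935)	DGPf_0F	CATCGCAATCGCACRATGATY	DGPf_0R	GAAAGTCTTGACCAGCARVAG	64.0	139	750	612
DGPf_1	Type I secretion target (PSF113_RS30625)	DGPf_1F	TGCAGGRAGACGGSAARG	DGPf_1R	CCRAGGAAGCCCAGGGAN	64.0	632	1316	685
DGPf_2	FAD dependent oxidoreductase (PFL01_RS10805)	DGPf_2F	GTRGTSTTCATCGGBGGHGG	DGPf_2R	TGGCARTACCAGACGTTRTCCG	64.0	88	1088	1001
DGPf_3	Glutamine synthetase (PputUW4_01890)	DGPf_3F	CCATGGCCGACCACCACGTCATCATCAARC	DGPf_3R	GCAGTTCCCAGTCGGTKATBCGYCGGTCG	64.0	671	1351	681
DGPf_4	KWG repeat-containing protein (PFL_RS20920)	DGPf_4F	CGCTGATCCTCTCGTTGTCTGC	DGPf_4R	ACGCCCTTGTCCACATCG	64.0	32	1103	1072
DGPf_5	3-phosphoshikimate 1-carboxyvinyltransferase (PFLA506_RS14455)	DGPf_5F	CGGCGTGGGTGTCGATCRR	DGPf_5R	GAGTTCGCAGAAAACCGTGACCG	67.0	3	1117	1115
DGPf_6	LysR family transcriptional regulator (PFL_RS18605)	DGPf_6F	GCSTTGCGHTAYTTCCACGAGG	DGPf_6R	GCCAGGCTYTTCTGCACYTCC	67.0	28	707	680
DGPf_7	LysR family transcriptional regulator (PFLU_RS11255)	DGPf_7F	CYGARATCGAGGGGCTKTGGA	DGPf_7R	GCTGAARTCTGGVAGCAGGGC	64.0	11	755	745
DGPf_8	LuxR family transcriptional regulator (PCL1606_12410)	DGPf_8F	CCCACCGACAGCCAGCAACG	DGPf_8R	CGGTCTTGTCGCTGATGCCG	67.0	127	787	661
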