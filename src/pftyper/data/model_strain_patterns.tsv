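# Published PCR presence/absence patterns of model P. fluorescens complex
# strains and negative-control Pseudomonas / E. coli strains.
sample_id	DGPf_0	DGPf_1	DGPf_2	DGPf_3	DGPf_4	DGPf_5	DGPf_6	DGPf_7	DGPf_8
F113	+	+	-	-	-	-	-	-	-
Q2-87	+	+	-	-	-	-	-	-	-
Q8r1-96	+	+	-	-	-	-	-	-	-
NFM421	+	+	-	-	-	-	-	-	-
PCL1319	-	-	+	-	-	-	-	-	+
PCL1606	-	-	+	-	-	-	-	-	+
Pf-5	-	-	+	-	+	-	+	-	-
Pf0-1	+	-	+	-	-	-	-	-	-
SBW25	-	-	-	-	-	+	-	+	-
KT2440	-	-	+	-	-	-	-	-	-
DC3000	-	-	-	-	-	-	-	-	-
PAO1	-	-	-	-	-	-	-	-	-
DH5alpha	-	-	-	-	-	-	-	-	-
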