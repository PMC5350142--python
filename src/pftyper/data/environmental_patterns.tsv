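# Published PCR presence/absence patterns of metagenomic DNA from one soil
# sample and two rhizosphere samples (mixed-community union signals).
sample_id	DGPf_0	DGPf_1	DGPf_2	DGPf_3	DGPf_4	DGPf_5	DGPf_6	DGPf_7	DGPf_8
Soil_sample	+	-	-	+	-	+	-	+	-
Rhizosphere_1	+	+	+	+	-	+	-	+	-
Rhizosphere_2	+	-	+	+	-	+	-	+	+
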