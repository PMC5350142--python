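# Published PCR presence/absence patterns of 19 field isolates from
# rhizosphere, endosphere and soil (blind test of the marker panel).
sample_id	DGPf_0	DGPf_1	DGPf_2	DGPf_3	DGPf_4	DGPf_5	DGPf_6	DGPf_7	DGPf_8
EMC3	+	-	+	-	-	-	-	-	-
EMC5	+	-	+	-	-	-	-	-	-
RMT7	+	-	+	-	-	-	-	-	-
RMC4	+	-	+	-	-	-	-	-	-
RMC9	+	-	+	-	-	-	-	-	-
3.2	+	-	+	-	-	-	-	-	-
EMC11	+	-	+	+	-	-	-	-	-
RMT1	+	-	+	+	-	-	-	-	-
RMT2	+	-	+	+	-	-	-	-	-
RMC8	+	-	+	+	-	-	-	-	-
HFL1	+	-	+	+	-	-	-	-	-
HFL4	+	-	+	+	-	-	-	-	-
EMC7	-	-	-	-	-	+	-	+	-
EMT2	-	-	-	-	-	+	-	+	-
EMT8	-	-	-	-	-	+	-	+	-
RMT4	-	-	-	-	-	+	-	+	-
RMT12	-	-	-	-	-	+	-	+	-
RMP9	+	+	-	-	-	-	-	-	-
7.3	+	+	-	-	-	-	-	-	-
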