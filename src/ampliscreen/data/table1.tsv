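sample_id	taqman	kmer
PRL_164	SS	SS
PRL_165	rr	Sr
PRL_166	SS	SS
PRL_167	SS	SS
PRL_168	Sr	Sr
PRL_169	rr	Sr
PRL_170	Sr	Sr
PRL_171	Sr	Sr
PRL_172	rr	rr
PRL_173	rr	rr
PRL_174	SS	SS
PRL_175	SS	SS
PRL_176	SS	SS
PRL_177	rr	rr
PRL_178	SS	SS
PRS_6	SS	SS
PRS_7	Sr	Sr
PRS_8	SS	SS
PRS_9	Sr	SS
PRS_10	rr	rr
PRS_11	SS	SS
PRS_12	Sr	SS
PRS_13	SS	SS
PRS_14	SS	SS
PRS_17	Sr	SS
PRS_18	SS	rr
PRS_20	SS	SS
PRSI_1	SS	SS
PRSI_2	SS	SS
PRSI_4	SS	SS
PRSI_5	SS	Sr
PRSI_6	rr	Sr
PRSI_7	rr	SS
PRSI_8	SS	SS
PRSI_9	SS	rr
PRSI_10	rr	SS
PRSI_11	SS	SS
PRSI_12	SS	SS
PRSI_13	SS	SS
PRSI_14	SS	SS
PRSI_15	SS	SS
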