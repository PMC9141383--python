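# group_size	athlete	635
# group_size	non_athlete	722
group	locus	genotype	frequency
athlete	ANKK1	GG	0.652
athlete	ANKK1	AG	0.310
athlete	ANKK1	AA	0.038
athlete	APOE_e	e4+	0.289
athlete	APOE_e	e4-	0.711
athlete	APOE_rs405509	GG	0.258
athlete	APOE_rs405509	GT	0.487
athlete	APOE_rs405509	TT	0.255
athlete	BDNF_AS	CC	0.675
athlete	BDNF_AS	CT	0.289
athlete	BDNF_AS	TT	0.036
athlete	COMT	AA	0.248
athlete	COMT	AG	0.498
athlete	COMT	GG	0.254
athlete	MAPT	CC	0.047
athlete	MAPT	CT	0.357
athlete	MAPT	TT	0.596
athlete	NOS3	TT	0.376
athlete	NOS3	CT	0.476
athlete	NOS3	CC	0.148
non_athlete	ANKK1	GG	0.652
non_athlete	ANKK1	AG	0.306
non_athlete	ANKK1	AA	0.042
non_athlete	APOE_e	e4+	0.282
non_athlete	APOE_e	e4-	0.718
non_athlete	APOE_rs405509	GG	0.262
non_athlete	APOE_rs405509	GT	0.473
non_athlete	APOE_rs405509	TT	0.265
non_athlete	BDNF_AS	CC	0.663
non_athlete	BDNF_AS	CT	0.301
non_athlete	BDNF_AS	TT	0.036
non_athlete	COMT	AA	0.302
non_athlete	COMT	AG	0.474
non_athlete	COMT	GG	0.224
non_athlete	MAPT	CC	0.047
non_athlete	MAPT	CT	0.314
non_athlete	MAPT	TT	0.639
non_athlete	NOS3	TT	0.387
non_athlete	NOS3	CT	0.443
non_athlete	NOS3	CC	0.170
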