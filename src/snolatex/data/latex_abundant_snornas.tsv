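name	original_id	length	class	predicted_using	real_fc
HbsnoR1	comp134121_c0_seq4	71	C/D guide	snoScan	5273.50
HbsnoR2	comp135067_c1_seq25	91	C/D guide	snoScan	5142.20
HbsnoR3	comp133339_c1_seq1	80	C/D guide	snoScan	5110.30
HbsnoR4	comp127218_c0_seq2	112	C/D guide	snoScan	4702.82
HbsnoR5	comp134112_c0_seq38	106	C/D guide	snoScan	4036.87
HbsnoR6	comp138449_c0_seq9	98	C/D guide	snoScan	3803.49
HbsnoR7	comp136167_c0_seq2	85	C/D guide	snoScan	3440.23
HbsnoR8	comp127540_c0_seq7	114	C/D guide	snoScan	311.90
HbsnoR9	comp136053_c0_seq5	79	C/D guide	snoScan	98.57
HbsnoR10	comp112986_c0_seq1	105	C/D guide	snoScan	53.87
HbsnoR11	comp136053_c0_seq1	79	C/D guide	snoScan	44.37
HbsnoR12	comp55259_c0_seq1	90	C/D guide	snoScan	6.50
HbsnoR13	comp132131_c0_seq2	109	C/D guide	snoScan	5.73
HbsnoR14	comp125573_c0_seq3	129	C/D guide	snoScan	5.12
HbsnoR15	comp136113_c0_seq10	114	C/D guide	snoScan	4.51
HbsnoR16	comp132232_c0_seq2	158	C/D guide	snoScan	4.05
HbsnoR17	comp132541_c0_seq6	76	C/D guide	snoScan	3.57
HbsnoR18	comp131062_c0_seq3	103	C/D guide	snoScan	3.56
HbsnoR19	comp135337_c0_seq2	85	C/D guide	snoScan	3.04
HbsnoR20	comp130910_c0_seq1	70	C/D guide	CDSeeker	2.85
HbsnoR21	comp138599_c0_seq5	143	C/D guide	CDSeeker	2.84
HbsnoR22	comp123171_c0_seq1	130	orphan	CDSeeker	4.93
HbsnoR23	comp127086_c0_seq5	129	H/ACA guide	ACASeeker	12485.31
HbsnoR24	comp138286_c0_seq14	157	orphan	ACASeeker	14668.81
HbsnoR25	comp83639R_c0_seq3	145	orphan	ACASeeker	8562.99
HbsnoR26	comp125664_c0_seq1	161	orphan	ACASeeker	5303.07
HbsnoR27	comp86093_c0_seq1	122	orphan	ACASeeker	4788.97
HbsnoR28	comp117226_c0_seq1	137	orphan	ACASeeker	4759.08
HbsnoR29	comp133438_c0_seq17	145	orphan	ACASeeker	4527.53
HbsnoR30	comp135975_c0_seq12	131	orphan	ACASeeker	3567.82
HbsnoR31	comp89929_c0_seq2	142	orphan	ACASeeker	2788.92
HbsnoR32	comp136348_c1_seq1	124	orphan	ACASeeker	353.33
HbsnoR33	comp132848_c0_seq1	138	orphan	ACASeeker	226.49
HbsnoR34	comp113290_c0_seq3	121	orphan	ACASeeker	77.61
HbsnoR35	comp129581_c0_seq2	147	orphan	ACASeeker	60.00
HbsnoR36	comp132931_c0_seq2	122	orphan	ACASeeker	22.58
HbsnoR37	comp129581_c0_seq3	147	orphan	ACASeeker	17.36
HbsnoR38	comp115823_c0_seq1	125	orphan	ACASeeker	12.87
HbsnoR39	comp141150_c0_seq1	142	orphan	ACASeeker	10.58
HbsnoR40	comp137921_c0_seq3	143	orphan	ACASeeker	9.69
HbsnoR41	comp136512_c0_seq1	157	orphan	ACASeeker	8.06
HbsnoR42	comp136486_c0_seq1	141	orphan	ACASeeker	6.90
HbsnoR43	comp134776_c0_seq2	140	orphan	ACASeeker	5.84
HbsnoR44	comp137994_c0_seq3	135	orphan	ACASeeker	5.14
HbsnoR45	comp135572_c0_seq1	143	orphan	ACASeeker	4.97
HbsnoR46	comp137742_c0_seq1	149	guide	ACASeeker	4.44
HbsnoR47	comp131146_c0_seq2	152	orphan	ACASeeker	3.45
HbsnoR48	comp134726_c0_seq6	139	orphan	ACASeeker	3.44
HbsnoR49	comp135184_c1_seq2	156	orphan	ACASeeker	3.26
HbsnoR50	comp136849_c0_seq1	144	orphan	ACASeeker	2.41
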