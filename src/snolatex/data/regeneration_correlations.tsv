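snorna	rho
HbsnoR28	0.6039
HbsnoR43	0.0905
HbsnoR14	0.0707
HbsnoR49	0.0418
HbsnoR26	-0.0117
HbsnoR46	-0.0861
HbsnoR1	-0.1703
HbsnoR38	-0.2110
HbsnoR27	-0.2165
HbsnoR23	-0.2616
HbsnoR10	-0.3152
HbsnoR25	-0.3386
HbsnoR34	-0.3586
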