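step	snoscan_cd_guide	cdseeker_guide	cdseeker_orphan	acaseeker_guide	acaseeker_orphan	total
Primary prediction	11269	642	546	409	9259	22125
Removal of EST	1538	174	100	86	1728	3626
Differential expression	198	23	8	12	193	434
Removal of redundancy	172	18	7	11	147	355
High expression in latex	19	2	1	1	27	50
Semi-quantitative PCR	12	0	0	1	18	31
Related to latex regeneration	3	0	0	1	9	13
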