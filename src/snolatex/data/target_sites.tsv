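snorna	rrna	site	mtype
HbsnoR1	18S	U791	Nm
HbsnoR2	18S	A265	Nm
HbsnoR2	18S	G1074	Nm
HbsnoR2	18S	G1374	Nm
HbsnoR2	18S	A1749	Nm
HbsnoR2	28S	G2041	Nm
HbsnoR2	28S	G2079	Nm
HbsnoR2	28S	U2090	Nm
HbsnoR2	28S	G3252	Nm
HbsnoR3	28S	C1060	Nm
HbsnoR5	28S	A2808	Nm
HbsnoR6	28S	C111	Nm
HbsnoR7	18S	A1193	Nm
HbsnoR7	18S	A1423	Nm
HbsnoR8	18S	A203	Nm
HbsnoR11	18S	C242	Nm
HbsnoR11	28S	C865	Nm
HbsnoR11	28S	A1664	Nm
HbsnoR11	28S	U2041	Nm
HbsnoR12	18S	A1417	Nm
HbsnoR12	28S	A1482	Nm
HbsnoR13	28S	U2798	Nm
HbsnoR13	28S	A2801	Nm
HbsnoR13	28S	A3149	Nm
HbsnoR15	18S	U1539	Nm
HbsnoR15	18S	U1545	Nm
HbsnoR15	28S	A1512	Nm
HbsnoR15	28S	U2868	Nm
HbsnoR15	28S	U2900	Nm
HbsnoR19	28S	G301	Nm
HbsnoR23	28S	U2790	psi
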