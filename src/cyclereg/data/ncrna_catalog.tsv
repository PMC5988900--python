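ccna	multiple_tss	phase	tss	strand	0	20	40	60	80	100	120	140	annotation
CCNA_R0004	/	/	210993	-	5.5	3.9	8.0	4.8	12.8	2.2	3.7	4.2	Cell cycle regulated
CCNA_R0009	/	/	708218	+	105.7	136.7	42.0	88.7	64.2	92.4	93.0	58.9	Small non-coding RNA
CCNA_R0016	/	/	844332	+	32.2	19.0	43.0	63.0	59.6	28.2	61.4	46.6	Small non-coding RNA
CCNA_R0019	/	/	920752	-	11.3	2.9	1.0	1.3	1.0	8.4	1.8	4.2	Stationary phase
CCNA_R0025	3	/	1176006	+	214.0	13.2	262.0	360.4	275.7	10.1	356.7	551.2	Small non-coding RNA
CCNA_R0040	/	/	1645202	+	7.8	7.9	16.0	14.3	7.7	20.0	17.9	19.4	Small non-coding RNA
CCNA_R0063	/	/	2889177	+	261.6	112.8	312.0	266.9	192.6	215.9	341.6	207.5	Minimal medium
CCNA_R0111	/	/	622892	+	0.8	1.4	5.0	0.4	0.0	2.7	0.5	3.9	Small non-coding RNA
CCNA_R0112	/	/	626656	+	121.1	143.6	101.0	118.7	109.4	66.8	139.2	74.8	Small non-coding RNA
CCNA_R0134	/	/	1294595	+	12.7	42.8	67.0	28.7	64.7	25.8	70.1	70.2	Small non-coding RNA
CCNA_R0137	/	/	1387892	-	43.3	45.3	21.0	43.5	20.0	68.8	39.8	63.5	Small non-coding RNA
CCNA_R0141	/	/	1607996	-	7.4	0.2	1.0	7.4	0.0	1.0	3.7	7.8	Small non-coding RNA
CCNA_R0142	/	/	1682820	+	13.3	16.8	4.0	6.5	3.1	5.3	8.2	15.9	Small non-coding RNA
CCNA_R0145	/	/	1911195	+	5.3	10.1	1.0	6.5	10.8	13.8	10.5	11.3	Small non-coding RNA
CCNA_R0147	/	/	1986625	+	129.1	31.7	77.0	50.4	66.2	8.2	27.9	14.5	Small non-coding RNA
CCNA_R0170	/	/	2778348	+	15.8	15.7	18.0	30.9	23.6	18.1	27.0	21.2	Small non-coding RNA
CCNA_R0171	/	/	2800063	+	0.4	5.8	0.0	7.0	8.2	3.4	5.5	3.9	Small non-coding RNA
CCNA_R0173	/	/	2967588	-	9.8	16.6	0.0	15.6	10.8	29.0	10.5	13.1	Small non-coding RNA
CCNA_R0174	/	/	2977449	+	31.6	40.9	20.0	41.7	12.3	35.9	38.9	25.4	Small non-coding RNA
CCNA_R0182	/	/	3288242	+	94.8	93.8	130.0	201.3	120.2	118.0	200.1	115.7	Small non-coding RNA
CCNA_R0183	/	/	3294320	+	17.9	1.0	1.0	10.0	2.6	0.0	1.8	2.5	Small non-coding RNA
CCNA_R0188	/	/	3462949	+	117.2	86.2	40.0	104.3	70.3	47.3	76.0	104.8	Small non-coding RNA
CCNA_R0193	/	/	3699499	+	214.6	72.0	134.0	130.4	118.6	75.3	132.8	121.0	Small non-coding RNA
CCNA_R0018	/	G1	920425	+	86.2	24.6	10.0	48.3	49.8	18.8	32.1	25.4	Rich medium
CCNA_R0051	/	G1	2404309	+	281.3	162.6	148.0	140.8	102.7	203.6	141.9	91.7	Small non-coding RNA
CCNA_R0095	/	G1	4950	-	99.3	6.2	18.0	36.1	22.6	13.5	19.2	12.7	Small non-coding RNA
CCNA_R0123	/	G1	921719	-	9.2	4.6	1.0	3.9	2.6	1.4	0.5	4.2	Small non-coding RNA
CCNA_R0176	/	G1	3091482	-	231.0	41.2	8.0	3.9	2.6	10.1	23.8	16.6	Small non-coding RNA
CCNA_R0199	/	G1	3987216	+	89.0	15.4	14.0	28.3	21.1	16.6	23.4	52.2	Small non-coding RNA
CCNA_R0025	1	G1-G2	1176026	+	139.7	81.3	59.0	83.9	86.8	49.9	131.0	150.3	Small non-coding RNA
CCNA_R0025	2	G1-G2	1176040	-	500.6	58.7	3.0	12.2	42.1	56.9	254.1	392.0	Small non-coding RNA
CCNA_R0164	/	G1-G2	2608458	-	34.3	26.2	10.0	12.2	22.6	46.8	40.8	26.8	Small non-coding RNA
CCNA_R0050	/	G1-S	2397735	+	105.5	700.9	385.0	306.0	167.9	99.2	103.9	64.2	Cell cycle regulated
CCNA_R0117	/	G1-S	772628	+	30.6	84.5	70.0	110.0	49.8	49.7	62.7	73.4	Small non-coding RNA
CCNA_R0104	/	G2	362212	-	4.5	0.2	0.0	4.8	7.7	6.0	17.4	22.6	Small non-coding RNA
CCNA_R0165	/	G2	2672357	-	25.2	10.8	2.0	10.9	18.5	42.2	78.8	43.8	Small non-coding RNA
CCNA_R0093	/	S	3781500	-	8141.7	16080.3	26189.0	16986.4	21895.1	19086.7	20603.8	15762.8	Minimal medium
CCNA_R0094	/	S	182	-	55.0	15.4	2.0	46.1	181.3	314.6	176.3	118.9	Small non-coding RNA
CCNA_R0116	/	S	757263	-	11.1	276.7	480.0	793.3	448.8	325.5	180.9	190.9	Small non-coding RNA
CCNA_R0124	/	S	938932	+	98.9	180.7	268.0	390.4	297.3	309.6	220.7	290.8	Small non-coding RNA
CCNA_R0126	/	S	1081336	-	1.4	5.5	6.0	15.6	10.3	12.8	9.6	4.9	Small non-coding RNA
CCNA_R0139	/	S	1523958	+	5.7	16.9	25.0	19.6	22.6	16.6	27.9	18.7	Small non-coding RNA
CCNA_R0152	/	S	2086425	+	447.7	526.2	416.0	1091.9	547.4	439.4	580.6	777.0	Small non-coding RNA
CCNA_R0159	/	S	2434068	+	1.0	12.3	15.0	25.6	14.9	16.9	18.3	15.2	Small non-coding RNA
CCNA_R0163	/	S	2560042	-	4.9	84.7	108.0	134.3	78.0	56.0	30.2	55.0	Small non-coding RNA
CCNA_R0172	/	S	2940670	-	51.7	71.5	210.0	159.5	181.3	146.0	173.5	109.0	Small non-coding RNA
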