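ccna	tss	strand	ctra_full	ctra_half	ccrm	dnaa	gcra_peaks
CCNA_R0004	210993	-	0	1	0	0	0
CCNA_R0009	708218	+	0	4	0	0	1
CCNA_R0016	844332	+	0	0	0	1	0
CCNA_R0018	920425	+	0	0	0	0	0
CCNA_R0019	920752	-	0	0	0	0	1
CCNA_R0025	1176006	+	1	2	0	0	0
CCNA_R0025	1176026	+	1	2	0	0	0
CCNA_R0025	1176040	-	0	1	1	0	0
CCNA_R0040	1645202	+	0	0	2	0	0
CCNA_R0050	2397735	+	0	0	0	0	0
CCNA_R0051	2404309	+	0	1	0	0	0
CCNA_R0063	2889177	+	0	0	0	0	0
CCNA_R0093	3781500	-	0	0	0	0	1
CCNA_R0094	182	-	2	4	1	0	0
CCNA_R0095	4950	-	0	0	0	0	0
CCNA_R0104	362212	-	0	2	0	0	0
CCNA_R0111	622892	+	0	0	0	0	0
CCNA_R0112	626656	+	0	1	1	0	0
CCNA_R0116	757263	-	0	1	3	0	1
CCNA_R0117	772628	+	0	0	1	0	0
CCNA_R0123	921719	-	0	0	0	0	0
CCNA_R0124	938932	+	0	3	0	0	0
CCNA_R0126	1081336	-	0	0	1	0	0
CCNA_R0134	1294595	+	0	0	0	0	0
CCNA_R0137	1387892	-	0	1	0	0	0
CCNA_R0139	1523958	+	0	0	0	1	0
CCNA_R0141	1607996	-	0	0	0	0	0
CCNA_R0142	1682820	+	0	0	0	0	0
CCNA_R0145	1911195	+	0	0	1	0	0
CCNA_R0147	1986625	+	0	0	0	0	0
CCNA_R0152	2086425	+	0	1	2	0	0
CCNA_R0159	2434068	+	0	0	2	1	0
CCNA_R0163	2560042	-	0	1	2	0	1
CCNA_R0164	2608458	-	0	0	0	0	0
CCNA_R0165	2672357	-	0	1	2	0	0
CCNA_R0170	2778348	+	0	0	2	0	0
CCNA_R0171	2800063	+	2	4	0	0	0
CCNA_R0172	2940670	-	0	0	1	1	0
CCNA_R0173	2967588	-	0	1	0	1	0
CCNA_R0174	2977449	+	0	0	0	0	1
CCNA_R0176	3091482	-	0	0	1	0	0
CCNA_R0182	3288242	+	0	0	0	0	0
CCNA_R0183	3294320	+	0	0	0	0	0
CCNA_R0188	3462949	+	0	0	0	0	0
CCNA_R0193	3699499	+	0	0	0	1	0
CCNA_R0199	3987216	+	0	2	1	2	0
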