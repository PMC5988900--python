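ccna	phase	functions	significant_genes
CCNA_R0004	/	Pilus, flagellum, cell division	cpaE, maf
CCNA_R0009	/	Flagellum
CCNA_R0016	/	Cell cycle	hdaA
CCNA_R0019	/	Flagellum
CCNA_R0025	/	Flagellum, ppGpp	spoT
CCNA_R0040	/	Cell division	ftsK
CCNA_R0063	/	Cell division	ftsH
CCNA_R0111	/	Flagellum, pilus, cell division	cpaE, cpaF, ftsK
CCNA_R0112	/	/
CCNA_R0134	/	Chromosome partitioning, cell division	mipZ, ftsY
CCNA_R0137	/	/
CCNA_R0141	/	Cell division, cell cycle	ftsH, tipN
CCNA_R0142	/	/
CCNA_R0145	/	Cell cycle, flagellum	hdaA, divL
CCNA_R0147	/	Cell division	ftsE
CCNA_R0170	/	Cell cycle, flagellum	hdaA
CCNA_R0171	/	Cell cycle, cell division, pilus	divJ, cpdR, mraZ, cpaD
CCNA_R0173	/	Cell cycle	podJ
CCNA_R0174	/	Flagellum
CCNA_R0182	/	/
CCNA_R0183	/	Cell division, flagellum	ftsI
CCNA_R0188	/	Pilus, cell cycle	cpaE, divL, hdaA
CCNA_R0193	/	Flagellum
CCNA_R0018	G1	Flagellum, cell division	ftsW
CCNA_R0051	G1	Flagellum
CCNA_R0095	G1	Pilus, flagellum, cell cycle, cell division, Chromosome partitioning	parA, cckA, ftsH, cpaE
CCNA_R0123	G1	Cell cycle, flagellum	dnaA
CCNA_R0176	G1	Cell cycle	dnaA, divJ
CCNA_R0199	G1	Stalk	shkA
CCNA_R0025	G1-G2	Flagellum, ppGpp	spoT
CCNA_R0025	G1-G2	Flagellum, ppGpp	spoT
CCNA_R0164	G1-G2	Flagellum
CCNA_R0050	G1-S	Cell cycle, flagellum	divJ, pleD, tipN
CCNA_R0117	G1-S	Flagellum
CCNA_R0104	G2	Cell cycle	dnaA, cenR
CCNA_R0165	G2	Cell cycle, flagellum, ppGpp	popZ, spoT
CCNA_R0093	S	Cell cycle	divL
CCNA_R0094	S	Cell cycle	dnaA
CCNA_R0116	S	Stalk	shkA
CCNA_R0124	S	Cell cycle	hdaA
CCNA_R0126	S	/
CCNA_R0139	S	Pilus, Flagellum, cell cycle	cpaF, divL, tacA, pleD
CCNA_R0152	S	/
CCNA_R0159	S	Cell cycle	dnaA
CCNA_R0163	S	Cell cycle	kidO
CCNA_R0172	S	Cell cycle	chpT
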