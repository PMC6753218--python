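# Pathogenic / likely pathogenic sequence variants of the reference
# infantile-onset epilepsy panel cohort (one row per diagnosed case).
case	gene	variant	inheritance	evidence	classification
Case 29	ARHGEF9	NM_001173479:c.1355G>A:p.Trp452*	From mosaic carrier mother	PVS1, PM2, PP1	Pathogenic
Case 75	ATP1A2	NM_000702:c.1096G>T:p.Gly366Cys	De novo	PS2, PM1, PM2, PP2, PP3	Pathogenic
Case 8	ATP1A3	NM_152296:c.1088T>C:p.Ile363Thr	Not evaluated	PM1, PM2, PM5, PP2, PP3	Likely Pathogenic
Case 5	GABRA1	NM_001127648:c.1015A>G:p.Lys339Glu	From asymptomatic mosaic mother	PM2, PM6+, PP2, PP3	Likely Pathogenic
Case 66	GABRB3	NM_001191320:c.577C>T:p.Leu193Phe	De novo	PS2, PM2, PP2, PP3	Likely Pathogenic
Case 2	GLRA1	NM_001292000:c.494_495insAC:p.Met165fs	From asymptomatic father	PVS1, PM2	Likely Pathogenic
Case 82	HCN1	NM_021072:c.1171G>A:p.Gly391Ser	De novo	PS2, PM2, PP2, PP3	Likely Pathogenic
Case 73	KCNA2	NM_004974:c.971G>A:p.Ser324Asn	De Novo	PS2, PM2, PP2, PP3	Likely Pathogenic
Case 85	KCNQ2	NM_004518:c.727C>G:p.Leu243Val	De novo	PS2, PM2, PP2, PP3	Pathogenic
Case 14	KCNQ2	NM_004518:c.766G>T:p.Gly256Trp	De novo	PS2, PM1, PM2, PP2, PP3, PP4	Pathogenic
Case 11	KCNQ2	NM_004518:c.997C>T:p.Arg333Trp	Not evaluated	PS2, PS4, PM2, PP2, PP3	Pathogenic
Case 57	KCNQ2	NM_004518:c.998G>A:p.Arg333Gln	From asymptomatic father	PS3, PS4, PM2, PP1, PP2	Pathogenic
Case 68	KCNQ2	NM_004518:c.1130dupC:p.Pro377fs	From asymptomatic father	PVS1, PM2, PP1	Pathogenic
Case 39	KCNQ3	NM_001204824:c.590T>C:p.Ile197Thr	From symptomatic father	PM1, PM2, PP1, PP2, PP3	Likely Pathogenic
Case 56	PCDH19	NM_001105243:c.595G>T:p.Glu199*	Not evaluated	PVS1, PM2	Likely Pathogenic
Case 96	PCDH19	NM_001105243:c.1105G>C:p.Ala369Pro	From asymptomatic father	PM2, PP1, PP2, PP3, PP4	Likely Pathogenic
Case 51	PRRT2	NM_001256442:c.649delC:p.Ala217fs	From asymptomatic father	PVS1, PS4, PM1	Pathogenic
Case 43	PRRT2	NM_001256442:c.649dupC:p.Ala217fs	From symptomatic father	PVS1, PS4, PM1, PP1	Pathogenic
Case 58	PRRT2	NM_001256442:c.649dupC:p.Ala217fs	Not evaluated	PVS1, PS4, PM1	Pathogenic
Case 71	PRRT2	NM_0012564:c.649dupC:p.Ala217fs	Not evaluated	PVS1, PS4, PM1	Pathogenic
Case 77	PRRT2	NM_001256442:c.649dupC:p.Ala217fs	Not evaluated	PVS1, PS4, PM1	Pathogenic
Case 78	PRRT2	NM_001256442:c.649dupC:p.Ala217fs	From asymptomatic father	PVS1, PS4, PM1	Pathogenic
Case 81	PRRT2	NM_001256442:c.649dupC:p.Ala217fs	From symptomatic mother	PVS1, PS4, PP1	Pathogenic
Case 83	PRRT2	NM_001256442:c.649dupC:p.Ala217fs	From symptomatic father	PVS1, PS4, PP1	Pathogenic
Case 105	PRRT2	NM_001256442:c.649dupC:p.Ala217fs	From symptomatic mother	PVS1, PS4, PP1	Pathogenic
Case 34	PRRT2	NM_001256442:c.796_797insGG:p.Arg266fs	From symptomatic father	PVS1, PS4, PP1	Pathogenic
Case 26	SCN1A	NM_001165963:c.596_602del:p.Thr199fs	Not evaluated	PVS1, PM2, PP4	Pathogenic
Case 101	SCN1A	NM_001165963:c.2244G>A:p.Trp748*	Not evaluated	PVS1, PS4, PM2, PP4	Pathogenic
Case 48	SCN1A	NM_001202435:c.2947-1G>A	Not evaluated	PVS1, PM2, PP4	Pathogenic
Case 40	SCN1A	NM_001165963:c.4201G>C:p.Glu1401Gln	Not evaluated	PM1, PM2, PP2, PP3, PP4	Likely Pathogenic
Case 13	SCN1A	NM_001165963:c.4219C>T:p.Arg1407*	Not evaluated	PVS1, PM2, PP4	Pathogenic
Case 54	SCN1A	NM_001165963:c.5288T>A:p.Ile1763Asn	From symptomatic mother	PS4, PM2, PP1, PP2, PP3, PP4	Pathogenic
Case 100	SCN1B	NM_001037:c.373C>T:p.Arg125Cys	Not evaluated	PS3, PM2, PP1, PP2, PP3	Pathogenic
Case 25	SCN2A	NM_001040143:c.466A>G:p.Lys156Glu	De novo	PS2, PM2, PP2, PP3, PP4	Likely Pathogenic
Case 45	SCN2A	NM_001040143:c.605C>T:p.Ala202Val	De novo	PS2, PM2, PP2, PP3	Likely Pathogenic
Case 33	SCN2A	NM_001040143:c.1879C>T:p.Gln627*	Not evaluated	PVS1, PM2	Likely Pathogenic
Case 31	SCN2A	NM_001040143:c.2932T>C:p.Phe978Leu	De novo	PS2, PM2, PP2, PP3	Likely Pathogenic
Case 104	SCN8A	NM_001177984:c.3820G>A:p.Val1274Met	De novo	PS2, PM2, PP2, PP3	Likely Pathogenic
Case 111	SCN8A	NM_014191:c.4423G>A:p.Gly1475Arg	Not evaluated	PM2, PP2, PP3, PP4, PP5	Likely Pathogenic
Case 79	SCN8A	NM_001177984:c.5491C>T:p.Arg1831Trp	De novo	PS2, PM2, PP2, PP3	Likely Pathogenic
Case 47	SLC2A1	NM_006516:c.223C>A:p.Gly75Arg	De novo	PS2, PM2, PP2, PP3	Likely Pathogenic
Case 12	SLC2A1	NM_006516:c.940G>C:p.Gly314Arg	Inherited from symptomatic mother	PM2, PM5, PP1, PP2, PP3	Likely Pathogenic
Case 93	SLC2A1	NM_006516:c.1255G>C:p.Gly419Arg	De novo	PS2, PM2, PP2, PP3	Likely Pathogenic
Case 17	STXBP1	NM_001032221:c.703C>T:p.Arg235*	De novo	PVS1, PS2, PM2	Pathogenic
Case 109	STXBP1	NM_001032221:c.1099C>T:p.Arg367*	Not evaluated	PVS1, PM2	Likely Pathogenic
Case 64	STXBP1	NM_001032221:c.1212A>C:p.Lys404Asn	De novo	PS2, PM2, PP2, PP3	Pathogenic
Case 1	SYNGAP1	NM_006772:c.2116-1G>A	De novo	PVS1, PS2, PM2	Pathogenic
Case 36	SYNGAP1	NM_006772:c.3718C>T:p.Arg1240*	De novo	PVS1, PS2, PM2	Pathogenic
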