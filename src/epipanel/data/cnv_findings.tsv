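# Pathogenic microdeletions of the reference cohort (all validated by
# chromosomal microarray). onset_days converts the printed onset age at
# 30.44 days per month.
case	locus	position_hg19	size_mb	involved_genes	onset_days	syndrome
Case 92	2q24.3 deletion	chr2:165755330-168986256	3.23	SCN2A,SCN1A,SCN9A	61	Dravet syndrome
Case 16	16p11.2 deletion	chr16:29652999-30198600	0.54	PRRT2	122	unclassified
Case 32	16p11.2 deletion	chr16:29673954-30119759	0.44	PRRT2	4	Benign infantile epilepsy
Case 18	20q13.33 deletion	chr20:61472348-62281707	0.80	CHRNA4,KCNQ2	61	unclassified
Case 80	20q13.33 deletion	chr20:61845191-62065069	0.21	CHRNA4,KCNQ2	1	Benign infantile epilepsy
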