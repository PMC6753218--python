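# Reference/variant read counts from deep amplicon validation of the three
# candidate mosaic variants in the reference cohort (panel = original capture
# sequencing, amplicon = barcoded amplicon resequencing; Mo/Fa = parents).
# printed_percent is the value as published; two amplicon cells of Case 61
# are arithmetically inconsistent with their counts (see consistent column).
case	gene	variant	assay	ref_count	var_count	printed_percent	decimals	consistent
Case 61	KCNQ2	c.643G>A:p.Gly215Arg	panel	1920	170	8.7	1	no
Case 61	KCNQ2	c.643G>A:p.Gly215Arg	amplicon	54190	9933	15.45	2	no
Case 61 (Mo)	KCNQ2	c.643G>A:p.Gly215Arg	amplicon	59508	137	0.23	2	yes
Case 61 (Fa)	KCNQ2	c.643G>A:p.Gly215Arg	amplicon	55091	128	0.23	2	yes
Case 42	SCN8A	c.2105G>C:p.Ser702Thr	panel	2427	167	6.4	1	yes
Case 42	SCN8A	c.2105G>C:p.Ser702Thr	amplicon	19035	4535	19.2	1	yes
Case 42 (Mo)	SCN8A	c.2105G>C:p.Ser702Thr	amplicon	15401	129	0.83	2	yes
Case 42 (Fa)	SCN8A	c.2105G>C:p.Ser702Thr	amplicon	17973	110	0.61	2	yes
Case 5	GABRA1	c.1015A>G:p.Lys339Glu	panel	1238	1242	50.1	1	yes
Case 5	GABRA1	c.1015A>G:p.Lys339Glu	amplicon	59872	53604	47.2	1	yes
Case 5 (Mo)	GABRA1	c.1015A>G:p.Lys339Glu	amplicon	100118	18074	15.3	1	yes
Case 5 (Fa)	GABRA1	c.1015A>G:p.Lys339Glu	amplicon	118255	1269	1.06	2	yes
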