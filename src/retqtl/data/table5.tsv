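# Chr 10 QTL candidate genes with SNPs fitting the haplotype B6 != C and
# A != C, transcribed from the published Chr 10 candidate list. fc columns
# are the microarray linear fold changes (C/B6a) at 4 and 8 months; "NP" =
# gene not present on the array. score_printed is the published "N criteria"
# column.
gene	posmed	fc_4m	fc_8m	score_printed
Heca	no	NP	NP	0
AC153433.6	no	NP	NP	0
Ccdc28a	no	1	1.3	1
Nhsl1	no	1	1	0
Hebp2	yes	NP	NP	1
Perp	yes	2.8	1	2
Tnfaip3	yes	1	1	1
D10Bwg1379e	no	1	1	0
Olig3	yes	NP	NP	1
Il20ra	no	NP	NP	0
Pex7	yes	0.8	1	2
Map3k5	yes	1	1	1
Mtap7	yes	1	1	1
Bclaf1	no	1	1	0
Pde7b	yes	NP	NP	1
Ahi1	yes	NP	NP	1
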