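# Chr 6 QTL candidate genes with SNPs fitting the haplotype B6 != C and A != C,
# transcribed from the published Chr 6 candidate list. fc columns are the
# microarray linear fold changes (C/B6a) at 4 and 8 months; "NP" = gene not
# present on the array. score_printed is the published "N criteria" column.
# Note: the printed score for Gkn1 (1) is inconsistent with its own inputs
# under the published scoring rule (PosMed = no, FC 1 / 0.9 is not regulated
# at the FC >= 1.2 / FC <= 0.8 boundaries), evidently a misprint in the
# source table; the row is transcribed as printed.
gene	posmed	fc_4m	fc_8m	score_printed
Fbln2	yes	1.8	1	2
Ctnna2	yes	NP	NP	1
Lrrtm4	no	1	1	0
Tacr1	yes	NP	NP	1
Hk2	yes	1	1	1
Sema4f	yes	NP	NP	1
Dok1	yes	1	1	1
Htra2	yes	1	1	1
Vax2	yes	NP	NP	1
Cyp26b1	yes	NP	NP	1
Rab11fip5	no	1	1	0
Alms1	yes	1	1	1
Tgfa	yes	1.4	1.8	2
Gmcl1	no	1	1.3	1
Anxa4	no	1	1	0
Aak1	yes	1	1	1
Nfu1	no	1	0.8	1
Gfpt1	yes	0.5	0.5	2
Antxr1	yes	1.4	1	2
Gkn1	no	1	0.9	1
Arhgap25	no	NP	NP	0
Ccdc48	no	NP	NP	0
Cnbp	no	1	1	0
Isy1	no	NP	NP	0
Gata2	yes	1	1	1
Eefsec	yes	1	1	1
Wnt7a	yes	NP	NP	1
Slc6a6	yes	0.8	1	2
Grip2	no	NP	NP	0
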