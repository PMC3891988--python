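# Published rice shoot-vs-root validation panel: 66 genes with paired
# microarray and qRT-PCR (2^-ddCt, Actin reference) log2 ratios.
gene_id	description	array_log2	qpcr_log2
Os07g29600	Zinc finger, C3HC4 type, domain containing protein, expressed	0.73	0.14
Os07g48180	bZIP transcription factor domain containing protein, expressed	-0.04	-0.7
Os08g15840	Ankyrin repeat-rich protein, putative, expressed	-0.99	-0.66
Os08g26880	bZIP transcription factor domain containing protein, expressed	1.42	1.19
Os08g03310	Zinc finger family protein, putative, expressed	4.58	4.99
Os08g33660	MYB family transcription factor, putative, expressed	3.93	2.8
Os09g35880	B-box zinc finger family protein, putative, expressed	0.93	0.97
Os09g33670	Zinc finger, C3HC4 type domain containing protein, expressed	-0.13	-0.12
Os09g36250	MYB family transcription factor, putative, expressed	0.75	0.2
Os09g30400	OsWRKY80 - Superfamily of TFs having WRKY and zinc finger domains, expressed	-0.17	-0.48
Os09g32510	BHLH transcription factor, putative, expressed	2.66	1.73
Os09g26400	Zinc finger, C3HC4 type domain containing protein, expressed	-0.17	-0.53
Os09g29960	Dof zinc finger domain containing protein, putative, expressed	2.57	2.71
Os10g33940	Auxin response factor 18, putative, expressed	-1.11	-0.32
Os12g13170	Transcription factor, putative, expressed	-0.08	0.66
Os12g31840	ZOS12-05 - C2H2 zinc finger protein, expressed	-0.45	-0.38
Os01g72330	OsRR4 type-A response regulator, expressed	2.53	2.42
Os01g70310	Inducer of CBF expression 2, putative, expressed	4.86	4.05
Os01g66420	PHD finger protein, putative, expressed	0.02	-0.28
Os02g02290	SNF2 family N-terminal domain containing protein, expressed	0.14	0.11
Os01g59660	MYB family transcription factor, putative, expressed	-1.41	-0.76
Os01g48130	No apical meristem protein, putative, expressed	0.31	-0.02
Os02g05510	GATA transcription factor 25, putative, expressed	-0.53	-0.09
Os02g35600	PHD finger protein, putative, expressed	2.08	0.74
Os02g29550	AP2 domain containing protein, expressed	0.42	1.23
Os02g55320	Two-component response regulator, putative, expressed	0.84	0.46
Os02g52340	OsMADS22 - MADS-box family gene with MIKCc type-box, expressed	2.78	2.13
Os02g50480	Histidine kinase, putative, expressed	0.12	0.49
Os03g43800	DIRP family protein, putative, expressed	-0.18	0.21
Os03g20550	OsWRKY55 - Superfamily of TFs having WRKY and zinc finger domains, expressed	-2.11	-2.45
Os03g61640	ZOS3-23 - C2H2 zinc finger protein, expressed	-0.64	0.3
Os03g60080	NAC domain-containing protein 67, putative, expressed	-4.04	-4.17
Os04g49450	MYB family transcription factor, putative, expressed	-2.27	-2.01
Os04g57610	Auxin response factor, putative, expressed	1.17	1.13
Os04g58020	MYB_Al protein, putative, expressed	0.1	-0.12
Os06g03580	Zinc RING finger protein, putative, expressed	-2.82	-2.41
Os05g46370	bHelix-loop-helix transcription factor, putative, expressed	-0.55	-0.81
Os05g37170	Transcription factor, putative, expressed	-2.58	-1.44
Os06g24070	myb-like DNA-binding domain containing protein, expressed	4.09	4.63
Os06g33810	Zinc finger protein, putative, expressed	0.27	-0.25
Os06g41390	N-terminal asparagine amidohydrolase, putative, expressed	-0.6	-0.02
Os03g55270	TIP41, putative, expressed	-0.73	-0.5
Os01g04800	B3 DNA binding domain containing protein, expressed	-3.02	-2.99
Os01g04120	ZOS1-03 - C2H2 zinc finger protein, expressed	-3.41	-4.35
Os01g11550	TCP family transcription factor, putative, expressed	2.09	3
Os07g48410	RNA-binding zinc finger protein, putative, expressed	0.68	0.85
Os07g38030	GRAS family transcription factor domain containing protein, expressed	1.77	1.44
Os07g49460	Response regulator receiver domain containing protein, expressed	-1.54	-0.69
Os08g40900	Auxin response factor, putative, expressed	-0.82	0.55
Os09g21180	Homeobox associated leucine zipper, putative, expressed	1.06	0.23
Os10g42130	No apical meristem protein, putative, expressed	-0.03	-0.19
Os01g74410	MYB family transcription factor, putative, expressed	-4.45	-3.84
Os01g55150	bZIP transcription factor domain containing protein, expressed	0.18	0.15
Os02g08440	OsWRKY71 - Superfamily of TFs having WRKY and zinc finger domains, expressed	-5.14	-2.75
Os02g43790	Ethylene-responsive transcription factor, putative, expressed	-4.02	-1.47
Os02g42380	TCP family transcription factor, putative, expressed	4.84	4.24
Os02g54830	RING-H2 finger protein, putative, expressed	0.35	-0.04
Os02g47810	Dof zinc finger domain containing protein, putative, expressed	2.99	1.97
Os03g09170	Ethylene-responsive transcription factor, putative, expressed	-5.3	-3.76
Os03g08960	Homeobox associated leucine zipper, putative, expressed	3.17	2.13
Os02g51280	TCP-domain protein, putative, expressed	0.05	0.4
Os03g17570	Response regulator receiver domain containing protein, expressed	-1.86	-1.42
Os03g60560	ZOS3-21 - C2H2 zinc finger protein, expressed	-5.18	-6.27
Os05g04820	MYB family transcription factor, putative, expressed	0.68	0.7
Os05g36290	Actin, putative, expressed	-0.97	0
Os06g12230	TCP-domain protein, putative, expressed	0.89	0.29
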