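# Published GO biological-process report rows for the rice shoot-vs-root
# contrast: term member counts and cluster percentages as printed.
# Note: the root-specific block was printed with cluster_size 438 although
# the accompanying text reports 463 root-specific genes; percentages in
# that block recompute from 438 (see docs/methods.md).
cluster	cluster_size	term	count	percentage
up_regulated	3138	Oxidation reduction	136	4.33
up_regulated	3138	Photosynthesis	36	1.15
up_regulated	3138	Photosynthesis, light harvesting	10	0.32
up_regulated	3138	Pigment metabolic process	13	0.41
up_regulated	3138	Pigment biosynthetic process	12	0.38
up_regulated	3138	Photosynthesis, light reaction	12	0.38
up_regulated	3138	Generation of precursor metabolites and energy	36	1.15
up_regulated	3138	Fatty acid biosynthetic process	14	0.45
up_regulated	3138	Fatty acid metabolic process	15	0.48
up_regulated	3138	Electron transport chain	14	0.45
up_regulated	3138	Aminoglycan metabolic process	7	0.22
up_regulated	3138	Lipid biosynthetic process	21	0.67
up_regulated	3138	Cellular aldehyde metabolic process	4	0.13
up_regulated	3138	Lipid transport	12	0.38
up_regulated	3138	Lipid localization	12	0.38
shoot_specific	438	Oxidation reduction	40	9.13
shoot_specific	438	Fatty acid metabolic process	8	1.83
shoot_specific	438	Recognition of pollen	6	1.37
shoot_specific	438	Pollination	6	1.37
shoot_specific	438	Cell recognition	6	1.37
shoot_specific	438	Pollen-pistil interaction	6	1.37
shoot_specific	438	Fatty acid biosynthetic process	7	1.60
shoot_specific	438	Reproductive cellular process	6	1.37
shoot_specific	438	Regulation of transcription	30	6.85
down_regulated	3845	Regulation of transcription	110	2.86
down_regulated	3845	Regulation of transcription, NA-dependent	71	1.85
down_regulated	3845	Regulation of RNA metabolic process	71	1.85
down_regulated	3845	Transcription	65	1.69
down_regulated	3845	Response to oxidative stress	27	0.70
down_regulated	3845	Oxidation reduction	81	2.11
down_regulated	3845	Cell wall polysaccharide metabolic process	5	0.13
down_regulated	3845	Oxylipin metabolic process	5	0.13
down_regulated	3845	Xylan metabolic process	5	0.13
down_regulated	3845	Xylan catabolic process	5	0.13
down_regulated	3845	Oxylipin biosynthetic process	5	0.13
root_specific	438	Response to oxidative stress	11	2.51
root_specific	438	Oxidation reduction	27	6.16
root_specific	438	Cell wall polysaccharide metabolic process	4	0.91
root_specific	438	Xylan metabolic process	4	0.91
root_specific	438	Hemicellulose metabolic process	4	0.91
root_specific	438	Xylan catabolic process	4	0.91
root_specific	438	Regulation of transcription	27	6.16
root_specific	438	Polysaccharide metabolic process	8	1.83
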