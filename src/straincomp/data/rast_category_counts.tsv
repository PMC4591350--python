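# Published RAST functional-category counts for R. opacus R7 and
# Rhodococcus sp. BCP1 (number of functions per category).
category	R7	BCP1
Cofactors, Vitamins, Prosthetic Groups, Pigments	665	429
Cell Wall and Capsule	111	80
Virulence, Disease and Defense	124	104
Potassium metabolism	17	24
Miscellaneous	115	81
Phages, Prophages, Transposable elements, Plasmids	0	7
Membrane Transport	108	92
Iron acquisition and metabolism	16	16
RNA metabolism	106	87
Nucleosides and Nucleotides	156	102
Protein Metabolism	257	230
Cell Division and Cell Cycle	35	27
Motility and Chemotaxis	5	4
Regulation and Cell signaling	75	51
Secondary Metabolism	13	7
DNA metabolism	103	124
Fatty Acids, Lipids and Isoprenoids	745	415
Nitrogen Metabolism	71	38
Dormancy and Sporulation	3	3
Respiration	221	158
Stress Response	162	138
Metabolism of Aromatic Compounds	267	128
Amino Acids and Derivatives	995	565
Sulphur Metabolism	126	58
Phosphorus Metabolism	35	32
Carbohydrates	1236	623
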