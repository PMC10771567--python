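pathway_id	pathway_name	compound_id
arginine_biosynthesis	Arginine biosynthesis	arginine
arginine_biosynthesis	Arginine biosynthesis	glutamic_acid
arginine_biosynthesis	Arginine biosynthesis	citric_acid
tca_cycle	Citrate cycle (TCA cycle)	citric_acid
tca_cycle	Citrate cycle (TCA cycle)	glutamic_acid
retinol_metabolism	Retinol metabolism	beta_carotene
phe_metabolism	Phenylalanine metabolism	phenylalanine
phe_metabolism	Phenylalanine metabolism	tyrosine
trp_metabolism	Tryptophan metabolism	tryptophan
phe_tyr_trp_biosynthesis	Phenylalanine, tyrosine and tryptophan biosynthesis	phenylalanine
phe_tyr_trp_biosynthesis	Phenylalanine, tyrosine and tryptophan biosynthesis	tyrosine
phe_tyr_trp_biosynthesis	Phenylalanine, tyrosine and tryptophan biosynthesis	tryptophan
val_leu_ile_degradation	Valine, leucine and isoleucine degradation	isoleucine
beta_alanine_metabolism	beta-Alanine metabolism	histidine
beta_alanine_metabolism	beta-Alanine metabolism	glutamic_acid
ala_asp_glu_metabolism	Alanine, aspartate and glutamate metabolism	glutamic_acid
ala_asp_glu_metabolism	Alanine, aspartate and glutamate metabolism	citric_acid
arg_pro_metabolism	Arginine and proline metabolism	arginine
arg_pro_metabolism	Arginine and proline metabolism	glutamic_acid
cys_met_metabolism	Cysteine and methionine metabolism	methionine
gly_ser_thr_metabolism	Glycine, serine and threonine metabolism	glycine
gly_ser_thr_metabolism	Glycine, serine and threonine metabolism	threonine
glyoxylate_metabolism	Glyoxylate and dicarboxylate metabolism	citric_acid
glyoxylate_metabolism	Glyoxylate and dicarboxylate metabolism	glycine
glyoxylate_metabolism	Glyoxylate and dicarboxylate metabolism	glutamic_acid
starch_sucrose_metabolism	Starch and sucrose metabolism	glucose
glycolysis	Glycolysis / Gluconeogenesis	glucose
fructose_mannose_metabolism	Fructose and mannose metabolism	mannose
fructose_mannose_metabolism	Fructose and mannose metabolism	glucose
fa_degradation	Fatty acid degradation	myristic_acid
fa_elongation	Fatty acid elongation	myristic_acid
unsat_fa_biosynthesis	Biosynthesis of unsaturated fatty acids	myristic_acid
steroid_biosynthesis	Steroid biosynthesis	cholesterol
primary_bile_acid_biosynthesis	Primary bile acid biosynthesis	cholesterol
primary_bile_acid_biosynthesis	Primary bile acid biosynthesis	glycine
glycerophospholipid_metabolism	Glycerophospholipid metabolism	phosphatidylcholine
pyrimidine_metabolism	Pyrimidine metabolism	thymine
histidine_metabolism	Histidine metabolism	histidine
histidine_metabolism	Histidine metabolism	glutamic_acid
nitrogen_metabolism	Nitrogen metabolism	glutamic_acid
d_gln_glu_metabolism	D-Glutamine and D-glutamate metabolism	glutamic_acid
aminoacyl_trna_biosynthesis	Aminoacyl-tRNA biosynthesis	methionine
aminoacyl_trna_biosynthesis	Aminoacyl-tRNA biosynthesis	tryptophan
aminoacyl_trna_biosynthesis	Aminoacyl-tRNA biosynthesis	tyrosine
aminoacyl_trna_biosynthesis	Aminoacyl-tRNA biosynthesis	glutamic_acid
aminoacyl_trna_biosynthesis	Aminoacyl-tRNA biosynthesis	glycine
aminoacyl_trna_biosynthesis	Aminoacyl-tRNA biosynthesis	arginine
aminoacyl_trna_biosynthesis	Aminoacyl-tRNA biosynthesis	phenylalanine
aminoacyl_trna_biosynthesis	Aminoacyl-tRNA biosynthesis	histidine
aminoacyl_trna_biosynthesis	Aminoacyl-tRNA biosynthesis	threonine
aminoacyl_trna_biosynthesis	Aminoacyl-tRNA biosynthesis	isoleucine
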