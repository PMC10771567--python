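wavenumber_cm1	metabolite	mode	class	compound_id	primary_peak
681	Methionine	CO2-scissoring and deformation	amino acid	methionine	1
701	Cholesterol	Choline group, CH2 rocking	lipid/FA	cholesterol	1
718	Phosphatidylcholine	Asymmetric stretching of N+(CH3)3	lipid/FA	phosphatidylcholine	1
743	Thymine (DNA bases)	Backbone vibrations, deformation of the ring	nucleic acid	thymine	1
757	Tryptophan	Symmetric breathing of tryptophan, sigma(ring)	amino acid	tryptophan	0
805	DNA, RNA	Symmetric breathing, C-C stretching	nucleic acid	generic	0
835	Tyrosine	Asymmetric O-P-O stretching	amino acid	tyrosine	1
848	Sugars (Glucose, Glycerol)	C-O-C skeletal stretching	carotenoid/sugar/carbohydrate	glucose	0
876	Glutamic acid	C-O-C ring, C-O-H bending	amino acid	glutamic_acid	1
898	Glycine	CH2 wagging vibrations from backbone	amino acid	glycine	1
940	Citric acid, Succinic acid	OH...O out-of-plane wagging of intermolecular hydrogen bonds	TCA	citric_acid	1
956	Lipids	C-H bending, C-C and C-O stretching	lipid/FA	myristic_acid	1
987	Arginine	C-N stretching	amino acid	arginine	1
1002	Phenylalanine	Symmetric ring breathing	amino acid	phenylalanine	1
1017	Carbohydrates	C-O-C ring, C-O-H bending	carotenoid/sugar/carbohydrate	generic	0
1031	Phenylalanine	C-H in-plane bending	amino acid	phenylalanine	0
1056	Lipids	Chain C-C stretching	lipid/FA	generic	0
1078	Lipids	Chain C-C stretching	lipid/FA	generic	0
1105	Mannose, Trehalose	CH2 twisting vibrations	carotenoid/sugar/carbohydrate	mannose	1
1126	Glucose	C-N stretching	carotenoid/sugar/carbohydrate	glucose	1
1154	Carotenoids	C-C and C-N stretching	carotenoid/sugar/carbohydrate	beta_carotene	1
1171	Saturated long-chain fatty acids	C-C stretching (skeletal)	lipid/FA	generic	0
1206	Amino acids	NH3 asymmetric rocking	amino acid	generic	0
1243	Amide III	Asymmetric phosphate stretching modes	protein	generic	0
1265	Unsaturated lipids and fatty acids	C-C and C-H stretching	lipid/FA	generic	0
1303	Triglycerides	CH3 CH2 twisting	lipid/FA	generic	0
1317	Histidine	C-S stretching, CH3/CH2 twisting or bending mode	amino acid	histidine	1
1340	Threonine	CH3/CH2 twisting/wagging mode	amino acid	threonine	1
1355	Isoleucine	CH3/CH2 wagging	amino acid	isoleucine	1
1420	DNA	C-S stretching of cytosine, C-C stretching, ring breathing mode	nucleic acid	generic	0
1517	Carotenoids	C-C and C-N stretching	carotenoid/sugar/carbohydrate	beta_carotene	0
1551	Tryptophan	Symmetric breathing, C-C stretching	amino acid	tryptophan	1
1584	Phenylalanine	C-C bending	amino acid	phenylalanine	0
1606	Phenylalanine	Ring C-C stretching, ring vibration	amino acid	phenylalanine	0
1617	Tyrosine	C=C stretching mode of tyrosine	amino acid	tyrosine	0
1657	Unsaturated lipids, phosphatidylcholine, phosphatidylethanolamine	C-C and C-O stretching	lipid/FA	phosphatidylcholine	0
1672	Amide I	C-C and C-O stretching	protein	generic	0
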