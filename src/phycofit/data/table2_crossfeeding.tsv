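gene_id	protein_name	function_label	mode	Rp+V	Rp+M	Rp+V+M
SPO0018	argininosuccinate synthase (argG)	Arginine	crossfeeding	3.5	3
SPO0332	argininosuccinate lyase (argH)	Arginine	crossfeeding	2.8
SPO0422	2-isopropylmalate synthase (leuA)	Leucine	crossfeeding		0.6
SPO0210	3-isopropylmalate dehydrogenase (leuB)	Leucine	crossfeeding			2.4
SPO0215	3-isopropylmalate dehydratase (leuD-1)	Leucine	crossfeeding	1.1		0.77
SPO1351	O-succinylhomoserine sulfhydrylase (metZ)	Homocysteine	crossfeeding	3
SPO1734	homoserine dehydrogenase (hom)	Homoserine	crossfeeding		5
SPO1884	S-methyltransferase component of split metH	Methionine	crossfeeding			3.9
SPO1973	3-dehydroquinate dehydratase, type II (aroQ)	Aromatic amino acids	crossfeeding	3.9
SPO2150	anthranilate phosphoribosyltransferase (trpD)	Tryptophan	crossfeeding	3.6		2.3
SPO2151	indole-3-glycerol phosphate synthase (trpC)	Tryptophan	crossfeeding	4.4
SPO3768	glutamate synthase (gltB)	Glutamate	crossfeeding	0.9		0.75
SPO2634	sulfite reductase	Amino acid - sulfur assimilation	crossfeeding	4.8
SPO2635	phosophoadenylyl-sulfate reductase (cysH)	Amino acid - sulfur assimilation	crossfeeding		4.2
SPO0102	3-methyl-2-oxobutanoate hydroxymethyltransferase (panB)	Vitamin B5	crossfeeding	0.43	0.42	0.44
SPO3224	cobalamin biosynthetic protein (cobC)	Vitamin B12	crossfeeding			6.2
SPO3633	molybdopterin converting factor, subunit 2	Molybdopterin	crossfeeding	0.41		0.3
SPO3634	molybdopterin converting factor, subunit 1 (moaD)	Molybdopterin	crossfeeding			0.3
SPO0284	dihydroorotase, multifunctional complex	Pyrimidine	crossfeeding			2.2
SPO2654	orotate phosphoribosyltransferase (pyrE)	Pyrimidine	crossfeeding	4.9
SPO1318	adenylosuccinate synthetase (purA)	Purine	crossfeeding		3.6	5.2
SPO1870	phosphoribosylformylglycinamidine synthase II (purL)	Purine	crossfeeding			3.1
SPO2168	phosphoribosylglycinamide formyltransferase (purN)	Purine	crossfeeding	1.6
SPO2677	amidophosphoribosyltransferase (purF)	Purine	crossfeeding	1.2
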