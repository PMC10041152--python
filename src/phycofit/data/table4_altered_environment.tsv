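gene_id	protein_name	function_label	mode	Rp+V	Rp+M	Rp+V+M
SPO3073	cytochrome c oxidase, subunit III (ctaE)	Aerobic respiration	altered_environment	0.43	0.33
SPO3075	Protoheme IX farnesyltransferase (ctaB)	Aerobic respiration	altered_environment	0.87	0.68	0.86
SPO3076	cytochrome c oxidase, subunit II (ctaC)	Aerobic respiration	altered_environment		0.47	0.49
SPO1383	cytochrome c oxidase, aa3-type, subunit I (ctaD)	Aerobic respiration	altered_environment	0.43
SPOA0212	nitric oxide reductase F protein	Respiration	altered_environment			0.31
SPO2099	cytochrome c-554 (cycF)	Respiration	altered_environment	-0.15
SPO1898	cytochrome P450 family protein	Respiration	altered_environment	-0.14
SPOA0223	cytochrome cd1 nitrite reductase (nirF)	Respiration	altered_environment	-0.17
SPO0935	nitroreductase family protein	Respiration	altered_environment			-0.17
SPO2340	superoxide dismutase, Fe (sodB)	Reactive oxygen species	altered_environment	1.7		2.1
SPO_Sp16SA	16S rRNA	Cell cycle/growth	altered_environment			0.11
SPO_Sp16SB	16S rRNA	Cell cycle/growth	altered_environment			0.13
SPO_Sp16SC	16S rRNA	Cell cycle/growth	altered_environment			0.14
SPO0503	ribosomal protein L30 (rpmD)	Cell cycle/growth	altered_environment			0.34
SPO1443	ATP-dependent RNA helicase RhlE (rhlE)	Cell cycle/growth	altered_environment	0.44	0.36	0.42
SPO3256	ribosomal protein L31 (rpmE)	Cell cycle/growth	altered_environment		3.9
SPO0691	GTP-binding protein Era (era)	Cell cycle/growth	altered_environment	0.78	0.84
SPO2819	NAD(P)+ transhydrogenase, beta (pntB)	Energy	altered_environment	0.39	0.36
SPO2820	NAD(P) transhydrogenase, alpha (pntA)	Energy	altered_environment			0.36
SPO0095	nicotinate phosphoribosyltransferase (pncB)	Energy	altered_environment	0.11
SPO1519	carbon monoxide dehydrogenase, large subunit (coxL-1)	Energy - carbon monoxide	altered_environment	-0.17		-0.23
SPO3901	carbon monoxide dehydrogenase G protein, putative	Energy - carbon monoxide	altered_environment			-0.31
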