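gene_id	protein_name	function_label	mode	Rp+V	Rp+M	Rp+V+M
SPO1240	type I secretion outer membrane protein (tolC)	Antimicrobial/Efflux	chemically_mediated	0.9		0.9
SPO1928	Tat (twin-arginine translocation) pathway signal sequence domain protein	Antimicrobial/Efflux	chemically_mediated		-0.13
SPO3091	type II secretion system protein F (gspF)	Antimicrobial/Efflux	chemically_mediated		-0.11	-0.13
SPO1757	capsular polysaccharide export protein (kpsS)	Efflux	chemically_mediated			-0.18
SPO2713	Protein translocase subunit SecA 2 (secA2)	Efflux	chemically_mediated		-0.42
SPO2251	gene transfer agent (orfg14)	Gene transfer	chemically_mediated	-0.84
SPO0071	competence protein F, putative	Gene transfer	chemically_mediated	-0.13		-0.2
SPOA0111	indolepyruvate oxidoreductase (iorA)	Signaling - auxin	chemically_mediated			-0.12
SPO2287	autoinducer synthesis protein	Signaling	chemically_mediated			0.12
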