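gene_id	protein_name	function_label	mode	Rp+V	Rp+M	Rp+V+M
SPO3479	glycolate oxidase (glcE)	Carbon source - Glycolate	competition	-0.44
SPO3805	Methylthioacryloyl-CoA hydratase (dmdD)	Carbon source - DMSP	competition		-0.11
SPO2708	carnitine dehydratase	Carbon/nitrogen source - carnitine	competition	-0.16
SPO1586	N-methylglutamate dehydrogenase (mgdC)	Carbon/nitrogen source - methylamine	competition		-0.18
SPO3360	2-amino-3-ketobutyrate co-A ligase (kbl)	Carbon/nitrogen source - threonine	competition			-0.12
SPO0673	taurine--pyruvate aminotransferase (tpa)	Carbon/nitrogen source - taurine	competition		-0.2
SPO0397	protein-P-II uridylyltransferase (glnD)	Nitrogen acquisition	competition			-6.5
SPO3661	allophanate hydrolase family protein	Nitrogen acquisition	competition	-0.24	-0.24	-0.29
SPO0891	alkylphosphonate utilization protein (phnM)	Phosphate acquisition	competition		-0.11
SPO1727	polyphosphate kinase 2, putative	Phosphate storage	competition			-2.2
SPO1213	oligopeptide ABC transporter, ATP-binding	Transporter - peptide	competition		-0.12
SPO2815	peptide/nickel/opine ABC transporter, permease	Transporter	competition	-0.12
SPO2816	peptide/nickel/opine ABC transporter, permease	Transporter	competition	-0.14
SPO1814	TRAP dicarboxylate transporter (dctP)	Transporter - organic acid	competition	-0.21	-0.2	-0.18
SPO1816	TRAP dicarboxylate transporter (dctM)	Transporter - organic acid	competition		-0.17	-0.18
SPO2626	TRAP transporter (dctM)	Transporter - organic acid	competition	-0.13		-0.12
SPO2627	C4 dicarbodylateTRAP transporter (dctQ)	Transporter - organic acid	competition	-0.17		-0.65
SPO2630	C4-dicarboxylate TRAP regulatory protein	Transporter - organic acid	competition	-0.25
SPOA0238	TRAP dicarboxylate transporter (dctP)	Transporter - organic acid	competition	-0.18	-0.2	-0.18
SPOA0240	TRAP transporter (dctM)	Transporter - organic acid	competition	-0.14	-0.14	-0.14
SPOA0237	C4-dicarboxylate transport transcriptional regulatory protein (dctD-2)	Transporter - organic acid	competition	-0.27	-0.25	-0.22
SPO0521	glutamate/glutamine/aspartate/asparagine ABC transporter, permease	Transporter - N-rich amino acid	competition			0.22
SPO0715	phosphocarrier protein HPr	Transporter - sugar	competition		1.2
SPOA0249	TRAP dicarboxylate transporter (dctP)	Transporter - organic acid	competition			0.13
SPO1496	ABC transporter, permease	Transporter	competition		0.38
SPOA0367	ABC transporter, permease	Transporter	competition	0.12
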