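cog_code	categories	descriptor
COG0001	H	Glutamate-1-semialdehyde aminotransferase
COG0002	E	N-acetyl-gamma-glutamylphosphate reductase
COG0008	J	Glutamyl- or glutaminyl-tRNA synthetase
COG0012	J	Ribosome-binding ATPase YchF, GTP1/OBG family
COG0013	J	Alanyl-tRNA synthetase
COG0016	J	Phenylalanyl-tRNA synthetase alpha subunit
COG0030	J	16S rRNA A1518/A1519 dimethyltransferase KsgA
COG0048	J	Ribosomal protein S12
COG0050	J	Translation elongation factor EF-Tu, GTPase
COG0060	J	Isoleucyl-tRNA synthetase
COG0085	K	DNA-directed RNA polymerase, beta subunit
COG0086	K	DNA-directed RNA polymerase, beta-prime subunit
COG0185	J	Ribosomal protein S19
COG0186	J	Ribosomal protein S17
COG0187	L	DNA gyrase/topoisomerase IV, subunit B
COG0188	L	DNA gyrase/topoisomerase IV, subunit A
COG0202	K	DNA-directed RNA polymerase, alpha subunit
COG0305	L	Replicative DNA helicase
COG0358	L	DNA primase
COG0417	L	DNA polymerase elongation subunit (family B)
COG0451	MG	Nucleoside-diphosphate-sugar epimerase
COG0468	L	RecA/RadA recombinase
COG0469	G	Pyruvate kinase
COG0480	J	Translation elongation factor EF-G, GTPase
COG0484	O	DnaJ-class molecular chaperone with C-terminal Zn finger domain
COG0513	LKJ	Superfamily II DNA and RNA helicase
COG0556	L	Excinuclease UvrABC helicase subunit UvrB
COG0568	K	RNA polymerase sigma factor RpoD
COG0587	L	DNA polymerase III, alpha subunit
COG0592	L	DNA polymerase III sliding clamp (beta) subunit
COG0593	L	Chromosomal replication initiation ATPase DnaA
COG0629	L	Single-stranded DNA-binding protein
COG0642	T	Signal transduction histidine kinase
COG0745	TK	DNA-binding response regulator, OmpR family
COG1196	D	Chromosome segregation ATPase Smc
COG1199	L	Rad3-related DNA helicase
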