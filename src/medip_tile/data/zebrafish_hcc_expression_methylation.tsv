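gene_name	symbol	chrom	expression	methylation	gene_id
Matrix metalloproteinase 14 (membrane-inserted) alpha	mmp14a	7	up	down	ENSDARG00000002235
Histidyl-tRNA synthetase	hars	14	up	down	ENSDARG00000003693
Tubulin, alpha 8 like 4	tuba8l4	6	up	down	ENSDARG00000006260
E2F transcription factor 6	e2f6	20	down	down	ENSDARG00000008119
Acetoacetyl-CoA synthetase	aacs	5	up	up	ENSDARG00000012468
Nucleophosmin 1	npm1	10	up	down	ENSDARG00000014329
Cell division protein kinase 8 (probe 54)	cdk8	24	up	down	ENSDARG00000016496
Cell division protein kinase 8 (probes 21, 31)	cdk8	24	up	up	ENSDARG00000016496
Hepatoma-derived growth factor-related protein 2	hdgfrp2	22	up	down	ENSDARG00000019530
RAB2A, member RAS oncogene family	rab2	2	up	down	ENSDARG00000020261
LIM domain containing preferred translocation partner in lipoma	lpp	6	up	down	ENSDARG00000023578
Insulin-like growth factor binding protein 5a	igfbp5b	9	down	down	ENSDARG00000025348
Mitogen-activated protein kinase 1	mapk1	5	up	down	ENSDARG00000027552
Cancer susceptibility candidate gene 3 protein homolog	casc3	3	up	up	ENSDARG00000029911
Hnrpa0l protein	hnrpa0l	14	up	down	ENSDARG00000036161
Cyclin T2	ccnt2	9	up	down	ENSDARG00000036685
Proliferating cell nuclear antigen	pcna	10	up	down	ENSDARG00000054155
Ret proto-oncogene (probes 16, 19)	ret	13	down	up	ENSDARG00000055305
Ret proto-oncogene (probes 20, 24)	ret	13	down	down	ENSDARG00000055305
Integrin-linked kinase (probes 8, 1)	ilk	10	up	down	ENSDARG00000056964
Integrin-linked kinase (probes 6)	ilk	10	up	up	ENSDARG00000056964
Novel protein similar to vertebrate threonyl-tRNA synthetase	tars	18	up	up	ENSDARG00000075429
Ribonuclease inhibitor 1	rnh1	22	down	down	ENSDARG00000078234
Calpain 2, (m/II) large subunit, like	capn2	22	up	down	ENSDARG00000034211
Synaptopodin-2	synp02	7	down	up	ENSDARG00000079675
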