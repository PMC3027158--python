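gene_name	gene_id	chrom	cgi_start	cgi_end	direction	category
Kruppel-like factor 12b	ENSDARG00000032197	9	31117162	31117483	hypo	proliferation
Insulin-like growth factor binding protein 5a	ENSDARG00000025348	9	49194032	49194791	hypo	proliferation
Insulin-like growth factor binding protein 2a	ENSDARG00000031422	9	49290381	49290816	hypo	proliferation
Insulin-like growth factor binding protein 1b	ENSDARG00000038666	2	178184	178306	hypo	proliferation
Insulin-like growth factor-binding protein 2A precursor	ENSDARG00000052470	6	22745784	22746301	hypo	proliferation
Estrogen related receptor delta fragment	ENSDARG00000015064	18	48225445	48225631	hypo	proliferation
Hypothetical protein LOC550398	ENSDARG00000043587	1	51038733	51038845	hypo	proliferation
Similar to SH2 domain containing 3C	ENSDARG00000028099	10	14303115	14303263	hypo	stress
PI-kinase-related SMG-1	ENSDARG00000054570	3	28544220	28544532	hypo	stress
Enolase 2	ENSDARG00000014287	19	4698036	4698168	hypo	glycolysis
Hexokinase 1	ENSDARG00000039452	13	23684991	23685203	hypo	glycolysis
c-Jun protein	ENSDARG00000043531	20	14274343	14274635	hypo	cell_cycle_metastasis_adhesion_growth_stress
BCL2-associated athanogene 5	ENSDARG00000017316	13	17324708	17324877	hypo	cell_cycle_metastasis_adhesion_growth_stress
Angiopoietin-like 3	ENSDARG00000044365	6	34165085	34165237	hypo	cell_cycle_metastasis_adhesion_growth_stress
Angiopoietin-1 receptor precursor	ENSDARG00000028663	5	625275	625436	hypo	cell_cycle_metastasis_adhesion_growth_stress
Ras homolog gene family, member Ua	ENSDARG00000019709	13	25136705	25136882	hypo	cell_cycle_metastasis_adhesion_growth_stress
Menage a trois homolog 1	ENSDARG00000002077	13	31141636	31142019	hypo	cell_cycle_metastasis_adhesion_growth_stress
Serine/threonine and tyrosine protein kinase	ENSDARG00000000853	22	461194	461772	hypo	cell_cycle_metastasis_adhesion_growth_stress
DNA (cytosine-5-)-methyltransferase 6	ENSDARG00000015566	17	34759411	34759539	hypo	dna_binding_transcription
Leucine zipper protein 2 precursor	ENSDARG00000068247	18	35625841	35625986	hypo	dna_binding_transcription
Histone H2A	ENSDARG00000001915	1	724191	724473	hypo	dna_binding_transcription
Histone deacetylase 4	ENSDARG00000041204	9	46375505	46375895	hypo	dna_binding_transcription
Homeobox protein Hox-B5a	ENSDARG00000013057	3	20707021	20707754	hypo	dna_binding_transcription
Pancreas transcription factor 1 subunit alpha	ENSDARG00000014479	2	27672474	27672641	hypo	dna_binding_transcription
Hypothetical protein LOC692291	ENSDARG00000012833	17	12689887	12690054	hypo	dna_binding_transcription
Metastasis associated 1 family, member 2	ENSDARG00000013031	7	17243535	17244290	hypo	dna_binding_transcription
Homeobox protein Hox-B4a	ENSDARG00000013533	3	20721064	20721722	hypo	dna_binding_transcription
Lysine-specific demethylase 4A	ENSDARG00000018782	6	4575451	4575994	hypo	dna_binding_transcription
RAB11 family interacting protein 4 (class II) a	ENSDARG00000053855	25	13380260	13380369	hypo	dna_binding_transcription
Hematopoietically-expressed homeobox protein hhex	ENSDARG00000074250	12	43558447	43558684	hyper	anti_angiogenesis
Hypothetical protein LOC678612	ENSDARG00000069505	21	27963202	27963305	hyper	cell_cell_adhesion
Novel protocadherin protein fragment	ENSDARG00000053462	1	55112983	55113251	hyper	cell_cell_adhesion
ATP-binding cassette, sub-family A, member 5	ENSDARG00000074041	12	38940033	38940251	hyper	transporter
Novel protein similar to nuclear factor, interleukin 3 regulated	ENSDARG00000071398	22	21400978	21401243	hyper	immune_system
Novel protein fragment	ENSDARG00000053462	1	55112983	55113251	hyper	immune_system
C5a anaphylatoxin chemotactic receptor	ENSDARG00000040319	18	45692130	45692420	hyper	immune_system
Vascular endothelial zinc finger 1	ENSDARG00000008247	10	35492470	35493037	hyper	angiogenesis_oxidative_stress
Coronin, actin binding protein 2ba	ENSDARG00000079440	7	33649014	33649398	hyper	membrane
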