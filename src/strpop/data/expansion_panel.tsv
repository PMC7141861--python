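# Packaged repeat-expansion screening panel: 31 disease-associated STR loci
# curated from the repeat-expansion-disorder literature.
# Coordinates: approximate GRCh38 positions of the repeat tract, treated as
# opaque by the code; thresholds in repeat copies.
chrom	start	end	motif	ref_units	marker_id	disease	threshold_units
chr4	3074877	3074933	CAG	19	HTT	Huntington disease	40
chrX	67545317	67545382	CAG	22	AR	Spinal and bulbar muscular atrophy	38
chr12	6936717	6936761	CAG	15	ATN1	Dentatorubral-pallidoluysian atrophy	48
chr6	16327636	16327722	CAG	29	ATXN1	Spinocerebellar ataxia 1	39
chr12	111598951	111599016	CAG	22	ATXN2	Spinocerebellar ataxia 2	33
chr14	92071011	92071052	CAG	14	ATXN3	Spinocerebellar ataxia 3	52
chr19	13207859	13207891	CAG	11	CACNA1A	Spinocerebellar ataxia 6	20
chr3	63912686	63912715	CAG	10	ATXN7	Spinocerebellar ataxia 7	37
chr13	70139384	70139428	CTG	15	ATXN8OS	Spinocerebellar ataxia 8	80
chr22	45795355	45795424	ATTCT	14	ATXN10	Spinocerebellar ataxia 10	800
chr5	146878729	146878758	CAG	10	PPP2R2B	Spinocerebellar ataxia 12	51
chr6	170561908	170562012	CAG	35	TBP	Spinocerebellar ataxia 17	49
chr16	66490398	66490447	TGGAA	10	BEAN1	Spinocerebellar ataxia 31	110
chr20	2652734	2652781	GGCCTG	8	NOP56	Spinocerebellar ataxia 36	650
chr1	57367044	57367093	ATTTC	10	DAB1	Spinocerebellar ataxia 37	31
chr16	87604288	87604329	CTG	14	JPH3	Huntington disease-like 2	40
chr19	45770205	45770219	CTG	5	DMPK	Myotonic dystrophy type 1	50
chr3	129172577	129172636	CCTG	15	CNBP	Myotonic dystrophy type 2	75
chrX	147912051	147912140	CGG	30	FMR1	Fragile X syndrome	200
chrX	148500638	148500682	CCG	15	AFF2	FRAXE intellectual disability	200
chr9	69037287	69037313	GAA	9	FXN	Friedreich ataxia	66
chr9	27573485	27573502	GGGGCC	3	C9orf72	C9orf72 ALS/frontotemporal dementia	31
chr4	41745973	41746032	GCG	20	PHOX2B	Congenital central hypoventilation syndrome	26
chrX	25013649	25013696	GCG	16	ARX	ARX-related developmental disorder	20
chr14	23321473	23321502	GCG	10	PABPN1	Oculopharyngeal muscular dystrophy	12
chr2	176093059	176093103	GCG	15	HOXD13	Synpolydactyly type II	22
chr18	55586155	55586199	CTG	15	TCF4	Fuchs endothelial corneal dystrophy	50
chr8	118366813	118366822	TTTCA	2	SAMD12	Familial adult myoclonic epilepsy 1	100
chr4	39348425	39348479	AAGGG	11	RFC1	CANVAS spectrum disorder	400
chr9	64839121	64839168	GGC	16	NOTCH2NLC	Neuronal intranuclear inclusion disease	60
chr19	14496041	14496085	GGC	15	GIPC1	Oculopharyngodistal myopathy type 2	70
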