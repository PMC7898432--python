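lg	bp	annotation
LG4	8276995	MVP1: Inactive GDSL esterase/lipase-like protein 25 (Arabidopsis thaliana)
LG4	8277387	GLIP5: GDSL esterase/lipase 5 (Arabidopsis thaliana)
LG4	8281294	B120: G-type lectin S-receptor-like serine/threonine-protein kinase B120 (Arabidopsis thaliana)
LG4	8283451	Protein of unknown function
LG4	8284126	DRG1: Developmentally-regulated G-protein 1 (Arabidopsis thaliana)
LG4	8302340	SARED1: Sanguinarine reductase (Eschscholzia californica)
LG4	8307120	EFL4: Protein ELF4-LIKE 4 (Arabidopsis thaliana)
LG4	8314410	TAF12B: Transcription initiation factor TFIID subunit 12b (Arabidopsis thaliana)
LG4	8326478	C1: Anthocyanin regulatory C1 protein (Zea mays)
LG4	8346564	ATG12: Ubiquitin-like protein ATG12 (Medicago truncatula)
LG4	8351941	WER: Transcription factor WER (Arabidopsis thaliana)
LG4	8360040	AIL1: AP2-like ethylene-responsive transcription factor AIL1 (Arabidopsis thaliana)
LG4	8374018	GRF5: Growth-regulating factor 5 (Arabidopsis thaliana)
LG4	8380107	GLP1: Germin-like protein subfamily 3 member 1 (Arabidopsis thaliana)
LG4	8382500	SPL2: E3 ubiquitin-protein ligase SPL2 (Arabidopsis thaliana)
LG4	8388401	TAF9: Transcription initiation factor TFIID subunit 9 (Arabidopsis thaliana)
LG4	8390867	RSH2: Probable GTP diphosphokinase RSH2, chloroplastic (Arabidopsis thaliana)
LG4	8402524	PSD: Exportin-T (Arabidopsis thaliana)
LG4	8408800	Cabp1: Calcium-binding protein 1 (Rattus norvegicus)
LG4	8418968	RIPK: Serine/threonine-protein kinase RIPK (Arabidopsis thaliana)
LG4	8430804	CYP75B1: Flavonoid 3'-monooxygenase (Arabidopsis thaliana)
LG4	8438631	LOX3.1: Linoleate 13S-lipoxygenase 3-1, chloroplastic (Solanum tuberosum)
LG4	8458547	GG3: Guanine nucleotide-binding protein subunit gamma 3 (Arabidopsis thaliana)
LG4	8462119	CCX4: Cation/calcium exchanger 4 (Arabidopsis thaliana)
LG4	8471534	ALDH7B4: Aldehyde dehydrogenase family 7 member B4 (Arabidopsis thaliana)
LG4	8477434	Protein of unknown function
LG4	8487623	DAGLA: Sn1-specific diacylglycerol lipase alpha (Homo sapiens)
LG4	8492535	RPL9: 60S ribosomal protein L9 (Pisum sativum)
LG7	3833896	Protein of unknown function
LG7	3840639	Coq9: Ubiquinone biosynthesis protein COQ9, mitochondrial (Drosophila melanogaster)
LG7	3852329	TIFY10A: Protein TIFY 10A (Arabidopsis thaliana)
LG7	3866715	MARD1: Protein MARD1 (Arabidopsis thaliana)
LG7	3882853	BGAL15: Beta-galactosidase 15 (Arabidopsis thaliana)
LG7	3890361	CPN20: 20 kDa chaperonin, chloroplastic (Arabidopsis thaliana)
LG7	3892877	ARF19: Auxin response factor 19 (Arabidopsis thaliana)
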