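symbol	canonical_id	gene_type	description	aliases
EWSR1	ENSG00000182944.19	protein_coding	EWS RNA binding protein 1	EWS|EWS-FLI1
SMARCA4	ENSG00000127616.19	protein_coding	SWI/SNF related chromatin remodeling ATPase, subfamily a, member 4	BRG1|SNF2B|SNF2L4
DDB2	ENSG00000134574.11	protein_coding	damage specific DNA binding protein 2	DDBB|UV-DDB2
YAP1	ENSG00000137693.15	protein_coding	Yes1 associated transcriptional regulator	YAP|YAP65
PSMD14	ENSG00000115233.11	protein_coding	proteasome 26S subunit, non-ATPase 14	RPN11|POH1
PEBP1	ENSG00000089220.11	protein_coding	phosphatidylethanolamine binding protein 1	RKIP|PBP
ITPKB	ENSG00000143772.11	protein_coding	inositol-trisphosphate 3-kinase B	IP3KB
ATF7IP	ENSG00000171681.14	protein_coding	activating transcription factor 7 interacting protein	MCAF1|AM
APOE	ENSG00000130203.10	protein_coding	apolipoprotein E	AD2
MAPT	ENSG00000186868.16	protein_coding	microtubule associated protein tau	TAU|MTBT1
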