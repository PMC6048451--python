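gene_symbol	drug_name
PSMA5	BORTEZOMIB
PSMA5	CARFILZOMIB
PSMD3	BORTEZOMIB
PSMD3	CARFILZOMIB
PSMB5	BORTEZOMIB
PSMB5	CARFILZOMIB
PSMB5	OPROZOMIB
JAK3	TOFACITINIB
JAK3	AT9283
JAK3	AZD1480
JAK3	PACRITINIB
JAK3	TOFACITINIB CITRATE
ARAF	SORAFENIB
ARAF	TRAMETINIB
ARAF	REGORAFENIB
ARAF	BMS-908662
ARAF	ADENOSINE TRIPHOSPHATE
HRAS	AZD8055
HRAS	EVEROLIMUS
HRAS	DB08751
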