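gene_a	gene_b	evidence_type
RAP2B	RAP2C	colocalization;shared_protein_domains
BRAF	RHEB	same_pathway;physical_interaction
RALA	UBE2K	co_expression
KRAS	RASSF2	physical_interaction
RGL2	KRAS	same_pathway;physical_interaction
RASSF2	APBB1IP	shared_protein_domains
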