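gene	protein_id	token	site_pos	peptide	group
ATXN1	P54253	Ser776Ala	772	IEPSKPAATRKRRWSAPESRK	II-
HSF1	Q00613	Ser303Ala	298	PLSSSPLVRVKEEPPSPPQSP	II-
LMNA	P02545	Gln203Gly	201	VDAENRLQTMKEELDFQKNIY	II-
USP25	Q9UHP3	Ile92Ala	99	TNVIDLTGDDKDDLQRAIALS	II-
USP39	Q53GS9	Lys6Arg	16	KRESRGSTRGKRESESRGSSG	II-
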