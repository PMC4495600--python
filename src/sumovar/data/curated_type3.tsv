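gene	protein_id	token	site_pos	peptide	group
CBX4	O00257	Thr497Ala	494	AGEPPSSLQVKPETPASAAVA	III
TP53	P04637	Phe385Ala	386	STSRHKKLMFKTEGPDSD	III
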