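accession	description	ushA_score	cpdB_score
CP090521.1	Pasteurella multocida strain AH09 chromosome, complete genome	628	98
NZ_CP038871.1	Pasteurella multocida strain FCf15 chromosome, complete genome	151	847
NZ_CP084165.1	Pasteurella multocida strain s4 chromosome, complete genome	67	851
NZ_CP020345.1	Pasteurella multocida subsp. multocida strain CIRMBP-0884 chromosome, complete genome	67	851
NZ_CP113522.1	Pasteurella multocida strain PF13 chromosome, complete genome	67	851
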