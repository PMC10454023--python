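accession	description	ushA_score	cpdB_score
NC_020163.1	Escherichia coli APEC O78, complete sequence	1102	1306
NZ_CP006834.2	Escherichia coli APEC O2-211 chromosome, complete genome	1098	1308
NZ_CP006830.1	Escherichia coli APEC O18 chromosome, complete genome	1097	1308
NZ_008563.1	Escherichia coli APEC O1, complete sequence	1097	1308
NZ_CP005930.1	Escherichia coli APEC IMT5155 chromosome, complete genome	592	1308
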