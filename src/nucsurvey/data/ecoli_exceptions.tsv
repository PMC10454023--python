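accession	description	ushA_score	cpdB_score
NZ_AP023205.1	Escherichia coli strain TUM18781 chromosome, complete genome	1100	88
NZ_CP128950.1	Escherichia coli strain TUM2805 chromosome, complete genome	1100	86
CP054239.1	Escherichia coli strain STO_Bone7 chromosome, complete genome	769	73
CP061232.1	Escherichia coli strain STEC639 chromosome, complete genome	678	71
AP027461.1	Escherichia coli str. K-12 substr. MG1655 D41c DNA, complete genome	87	1308
AP027460.1	Escherichia coli str. K-12 substr. MG1655 D37c16 DNA, complete genome	87	1308
AP027459.1	Escherichia coli str. K-12 substr. MG1655 D37c146 DNA, complete genome	87	1308
AP027458.1	Escherichia coli str. K-12 substr. MG1655 D37c145 DNA, complete genome	87	1308
AP027457.1	Escherichia coli str. K-12 substr. MG1655 D37c143 DNA, complete genome	87	1308
AP027456.1	Escherichia coli str. K-12 substr. MG1655 D37c13 DNA, complete genome	87	1308
AP027455.1	Escherichia coli str. K-12 substr. MG1655 D37b DNA, complete genome	87	1308
AP027454.1	Escherichia coli str. K-12 substr. MG1655 D33b DNA, complete genome	87	1308
AP027453.1	Escherichia coli str. K-12 substr. MG1655 D33a DNA, complete genome	87	1308
NC_011750.1	Escherichia coli IAI39, complete sequence	118	1307
CP042982.1	Escherichia coli strain NCCP 14540 chromosome, complete genome	88	1306
CP061269.1	Escherichia coli strain STEC1012 chromosome, complete genome	87	1305
CP099173.1	Escherichia coli strain RHB23-SO-C02 chromosome, complete genome	87	1303
NZ_AP027411.1	Escherichia coli strain EC521 isolate EC521 chromosome, complete genome	87	1300
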