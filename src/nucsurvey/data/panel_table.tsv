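no	accession	description	length_aa	kind	selected
1	P07024	USHA_ECOLI [Escherichia coli]	550	UshA-like	1
2	Q9KQ30	5'-nucleotidase [Vibrio cholerae]	553	UshA-like	0
3	WP_005182369	UDP-sugar hydrolase/5'-nucleotidase UshA [Yersinia intermedia]	550	UshA-like	0
4	Q8EFH1	5'-nucleotidase [Shewanella oneidensis]	569	UshA-like	0
5	AAF12718	UDP-sugar hydrolase precursor [Klebsiella aerogenes]	550	UshA-like	0
6	P44569	NAD 5'-nucleotidase [Haemophilus influenzae]	603	UshA-like	1
7	WP_061821283	LPXTG-anchored adenosine synthase AdsA [Staphylococcus aureus]	772	UshA-like	0
8	WP_011837008	Cell surface ecto-5'-nucleotidase Nt5e [Streptococcus sanguinis]	719	UshA-like	1
9	WP_000726911	Bifunctional metallophosphatase/5'-nucleotidase [Streptococcus agalactiae]	690	UshA-like	1
10	AEJ25391	Surface-anchored 5'-nucleotidase [Streptococcus equi]	668	UshA-like	0
11	Q9A0A2	Putative secreted 5'-nucleotidase [Streptococcus pyogenes]	670	UshA-like	0
12	CAR45827	Putative 5'-nucleotidase [Streptococcus suis P1/7]	721	UshA-like	0
13	WP_003099850	5'-Nucleotidase C-terminal domain-containing protein [Streptococcus iniae]	676	UshA-like	0
14	Q6HTQ7	2',3'-Cyclic-nucleotide 2'-phosphodiesterase [Bacillus anthracis]	780	CpdB-like	0
15	P22848	5'-Nucleotidase [Vibrio parahaemolyticus]	560	UshA-like	0
16	WP_102505627	UDP-sugar hydrolase/5'-nucleotidase UshA [Salinivibrio costicola]	557	UshA-like	0
17	WP_041419915	UDP-sugar hydrolase/5'-nucleotidase UshA [Shewanella violacea]	569	UshA-like	0
18	WP_011760134	UDP-sugar hydrolase/5'-nucleotidase UshA [Shewanella amazonensis]	571	UshA-like	0
19	O32133	Uncharacterized metallophosphoesterase YunD [Bacillus subtilis]	462	UshA-like	1
20	P08331	2',3'-Cyclic-nucleotide 2'-phosphodiesterase/3'-nucleotidase [Escherichia coli]	647	CpdB-like	1
21	AYV64543	Heme-binding protein SntA [Streptococcus suis]	813	CpdB-like	1
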