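species	n_total	n_U	n_C	n_both
Staphylococcus saprophyticus	17	17	4	4
Salmonella enterica ser. Typhimurium	350	219	219	219
Klebsiella pneumoniae	1967	1962	1962	1962
Vibrio cholerae	221	112	112	112
Pasteurella multocida	138	135	137	134
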