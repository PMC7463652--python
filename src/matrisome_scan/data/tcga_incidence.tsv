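tumor_type	new_cases_2020	deaths_2020	five_year_survival_pct
BRCA	279100	42690	91
CESC	13800	4290	69
COAD/READ	147950	53200	66
ESCA	18440	16700	21
LUSC/LUAD	228820	135720	21
OV	21750	13940	48
PAAD	57600	47050	10
PRAD	191930	33330	99
SKCM	100350	6850	94
STAD	27600	11010	32
UCS/UCEC	65620	12590	83
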