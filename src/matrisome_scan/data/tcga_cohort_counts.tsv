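tumor_type	n_patients	n_matrisome_cna	n_matrisome_mutation
BRCA	1236	773	749
CESC	312	276	278
COAD	545	270	288
READ	183	87	87
ESCA	204	181	183
LUAD	641	504	506
LUSC	623	473	475
OV	604	59	58
PAAD	196	156	155
PRAD	566	447	437
SKCM	479	359	356
STAD	511	424	429
UCEC	583	368	440
UCS	57	56	56
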