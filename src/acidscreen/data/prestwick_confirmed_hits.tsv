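compound	pct_inhibition	therapeutic_group
Chlorhexidine	96	Bacteriostatic
Camptothecin	92	Antitumor agent
Methyl benzethonium chloride	112	Antibacterial
Benzethonium chloride	110	Antibacterial
Thimerosal	66	Antiseptic
Alexidine dihydrochloride	110	Antibacterial
Simvastatin	81	Antihyperlipidemic
Auranofin	111	Antirheumatic
Thonzonium bromide	117	Antiseptic
Pyrvinium pamoate	90	Antiparasitic
Verteporfin	111	Treatment of age-related macular degeneration
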