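#category	include_patterns	exclude_patterns
monooxygenase	monooxygenase;mono-oxygenase
dioxygenase	dioxygenase
alcohol_dehydrogenase	alcohol dehydrogenase
aldehyde_dehydrogenase	aldehyde dehydrogenase
cytochrome_p450	cytochrome P450;cytochrome P-450
laccase	laccase
sulfide_quinone_oxidoreductase	sulfide:quinone oxidoreductase;sulfide quinone oxidoreductase
flavocytochrome_c_sulfide_dehydrogenase	flavocytochrome c sulfide dehydrogenase
sox_system	soxX;soxA;soxB;soxC;soxD;soxY;soxZ;sulfur oxidation protein sox
adenylylsulfate_reductase	adenylylsulfate reductase;adenylyl-sulfate reductase;APS reductase	adenylylsulfate:phosphate
dissimilatory_sulfite_reductase	dissimilatory sulfite reductase;siroheme sulfite reductase;re:\bdsr[A-Z]\b
sulfate_adenylyltransferase	sulfate adenylyltransferase
sulfite_oxidase	sulfite oxidase
sulfur_relay	sulfur relay protein;sulfur transfer protein
dienelactone_hydrolase	dienelactone hydrolase
haloacid_dehalogenase	haloacid dehalogenase
carboxymuconolactone_decarboxylase	carboxymuconolactone decarboxylase
beta_oxidation	acyl-CoA dehydrogenase;3-hydroxyacyl-CoA dehydrogenase;long-chain fatty acid CoA ligase;long-chain-fatty-acid--CoA ligase
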