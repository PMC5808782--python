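# Default major-tissue configuration: term id <TAB> name
# Override with --major-tissues on the CLI.
BTO:0001487	adipose tissue
BTO:0000089	blood
BTO:0000140	bone
BTO:0000141	bone marrow
BTO:0000282	eye
BTO:0000493	gall bladder
BTO:0000562	heart
BTO:0000648	intestine
BTO:0000671	kidney
BTO:0000759	liver
BTO:0000763	lung
BTO:0000887	muscle
BTO:0000925	nervous system
BTO:0000988	pancreas
BTO:0001203	salivary gland
BTO:0001253	skin
BTO:0001281	spleen
BTO:0001307	stomach
BTO:0001363	testis
BTO:0001379	thyroid gland
BTO:0001419	urine
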