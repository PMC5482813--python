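amphibian	Anolis_carolinensis
amphibian	Xenopus_tropicalis
fish	Danio_rerio
fish	Gasterosteus_aculeatus
bird	Gallus_gallus
fungi	Ustilago_maydis
fungi	Saccharomyces_cerevisiae
fungi	Neurospora_crassa
fungi	Schizosaccharomyces_pombe
plant	Vitis_vinifera
plant	Arabidopsis_thaliana
plant	Oryza_sativa
plant	Physcomitrella_patens
protist	Plasmodium_falciparum
protist	Dictyostelium_discoideum
protist	Leishmania_major
protist	Phaeodactylum_tricornutum
protist	Phytophthora_infestans
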