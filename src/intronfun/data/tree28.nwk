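((((((((((((((Homo_sapiens:7,Pan_troglodytes:7):9,Pongo_abelii:16):74,Mus_musculus:90):70,Monodelphis_domestica:160):20,Ornithorhynchus_anatinus:180):140,(Gallus_gallus:280,Anolis_carolinensis:280):40):32,Xenopus_tropicalis:352):83,(Danio_rerio:230,Gasterosteus_aculeatus:230):205):165,Ciona_savignyi:600):80,((Drosophila_melanogaster:530,Caenorhabditis_elegans:530):80,Schistosoma_mansoni:610):70):420,(((Saccharomyces_cerevisiae:520,Neurospora_crassa:520):60,Schizosaccharomyces_pombe:580):70,Ustilago_maydis:650):450):200,Dictyostelium_discoideum:1300):200,((((Arabidopsis_thaliana:117,Vitis_vinifera:117):43,Oryza_sativa:160):340,Physcomitrella_patens:500):950,((Phaeodactylum_tricornutum:500,Phytophthora_infestans:500):700,Plasmodium_falciparum:1200):250):50):100,Leishmania_major:1600);
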