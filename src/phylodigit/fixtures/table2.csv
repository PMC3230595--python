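# Substrate-use indices per species: proportion of individuals observed on
# each substrate type (sand, rocks, trunks, ground, perches). Rows sum to 1
# up to printed rounding.
species,family,sand,rocks,trunks,ground,perches
Eurolophosaurus_divaricatus,Tropiduridae,1.00,0.00,0.00,0.00,0.00
Plica_umbra,Tropiduridae,0.00,0.00,0.87,0.05,0.08
Tropidurus_cocorobensis,Tropiduridae,1.00,0.00,0.00,0.00,0.00
Tropidurus_etheridgei,Tropiduridae,1.00,0.00,0.00,0.00,0.00
Tropidurus_hispidus,Tropiduridae,0.00,0.95,0.04,0.01,0.00
Tropidurus_hygomi,Tropiduridae,0.90,0.00,0.00,0.00,0.10
Tropidurus_insulanus,Tropiduridae,0.00,1.00,0.00,0.00,0.00
Tropidurus_itambere,Tropiduridae,0.00,0.99,0.00,0.01,0.00
Tropidurus_montanus,Tropiduridae,0.00,0.82,0.05,0.13,0.00
Tropidurus_oreadicus,Tropiduridae,0.00,0.35,0.51,0.14,0.00
Tropidurus_psammonastes,Tropiduridae,1.00,0.00,0.00,0.00,0.00
Tropidurus_spinulosus,Tropiduridae,0.00,0.00,0.97,0.03,0.00
Uracentron_superciliosus,Tropiduridae,0.00,0.06,0.66,0.11,0.17
Anolis_fuscoauratus,Polychrotidae,0.00,0.00,0.42,0.16,0.42
Anolis_nitens,Polychrotidae,0.00,0.00,0.31,0.58,0.11
Anolis_olssoni,Polychrotidae,0.00,0.00,0.00,0.50,0.50
Anolis_ortonii,Polychrotidae,0.00,0.35,0.45,0.00,0.20
Anolis_punctatus,Polychrotidae,0.00,0.00,0.75,0.16,0.09
Anolis_transversalis,Polychrotidae,0.00,0.00,0.73,0.09,0.18
Enyalius_iheringii,Polychrotidae,0.00,0.00,0.25,0.25,0.50
Enyalius_perditus,Polychrotidae,0.00,0.00,0.50,0.00,0.50
Polychrus_acutirostris,Polychrotidae,0.00,0.00,0.25,0.00,0.75
Polychrus_marmoratus,Polychrotidae,0.00,0.00,0.25,0.05,0.70
Iguana_iguana,Iguanidae,0.00,0.00,0.35,0.30,0.35
Sauromalus_obesus,Iguanidae,0.00,1.00,0.00,0.00,0.00
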