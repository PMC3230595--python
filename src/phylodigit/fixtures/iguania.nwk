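# Composite rooted topology for the 25 iguanian species (no branch lengths;
# lengths are assigned analytically, see phylodigit.tree.assign_branch_lengths).
# Hand-assembled composite of published phylogenetic hypotheses for the
# study group: family-level arrangement with Iguanidae
# sister to (Polychrotidae, Tropiduridae); Tropiduridae after Frost et al.
# (2001), with (Plica, Uracentron) sister to Tropidurus and the torquatus
# species group nested inside Tropidurus; Polychrotidae with Polychrus sister
# to (Enyalius, Anolis) and Anolis after Poe (2004). Within-Anolis and
# within-torquatus-group resolutions are the transcriber's reading;
# ambiguous nodes were resolved toward the cited source hypotheses.
# Lines starting with '#' are comments; the remainder is standard newick.
(((Iguana_iguana,Sauromalus_obesus),((Polychrus_acutirostris,Polychrus_marmoratus),((Enyalius_perditus,Enyalius_iheringii),(Anolis_olssoni,((Anolis_punctatus,Anolis_transversalis),(Anolis_nitens,(Anolis_ortonii,Anolis_fuscoauratus))))))),(Eurolophosaurus_divaricatus,((Plica_umbra,Uracentron_superciliosus),(Tropidurus_spinulosus,(Tropidurus_etheridgei,((Tropidurus_cocorobensis,(Tropidurus_hygomi,Tropidurus_psammonastes)),(Tropidurus_montanus,(Tropidurus_itambere,(Tropidurus_oreadicus,(Tropidurus_hispidus,Tropidurus_insulanus))))))))));
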