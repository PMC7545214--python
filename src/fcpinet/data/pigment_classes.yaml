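# Default chemical-component code -> pigment class map.
# Codes follow the PDB Chemical Component Dictionary:
#   CLA  chlorophyll a
#   KC1  chlorophyll c1
#   KC2  chlorophyll c2
#   A86  fucoxanthin
#   DD6  diadinoxanthin
#   BCR  beta-carotene
# Component codes vary across depositions; edit or replace this file to
# match the structure being analysed.
CLA: chl_a
KC1: chl_c
KC2: chl_c
A86: fucoxanthin
DD6: diadinoxanthin
BCR: beta_carotene
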