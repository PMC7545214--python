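# Chain -> subunit annotation TEMPLATE for PDB 6LY5 (diatom PSI-FCPI).
#
# The publication fixes only two chain assignments explicitly:
#   chain h = PsaR, chain g = PsaS.
# The remaining core chains below follow the usual PDB convention of
# naming PSI core chains after their subunit letter; they have NOT been
# verified against the deposited file.  The 24 antenna chain IDs are the
# deposition's, not the publication's, and must be filled in by inspecting
# the deposited mmCIF (FCPI-1..FCPI-24 numbering is defined by the paper's
# figure panels, innermost ring first).
#
# Complete and verify this file before analysing 6LY5:
#   <chain id>: FCPI-1
#   ...
A: PsaA
B: PsaB
C: PsaC
D: PsaD
E: PsaE
F: PsaF
I: PsaI
J: PsaJ
L: PsaL
M: PsaM
h: PsaR
g: PsaS
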