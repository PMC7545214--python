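# Published pigment census of the diatom PSI-FCPI supercomplex (PDB 6LY5):
# ligand counts of the deposited model and the number of antenna subunits.
# Used by the pure-arithmetic census mode (`fcpinet census --counts ...`).
chl_a_total: 326
chl_a_core: 94
chl_c_total: 34
fx_total: 102
ddx_total: 35
bcr_total: 18
n_antennas: 24
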