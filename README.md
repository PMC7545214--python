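# fcpinet

Pigment-network analysis of photosystem I (PSI) antenna supercomplexes —
built around the diatom PSI–FCPI architecture, in which a 12-subunit PSI
core (PsaA/B/C/D/E/F/I/J/L/M plus PsaR and PsaS) is encircled by 24
fucoxanthin chlorophyll *a/c*-binding antenna proteins (FCPI-1…FCPI-24)
arranged in three concentric layers.

Given a coordinate file (mmCIF or PDB) plus two small configs (chain →
subunit labels, chemical-component code → pigment class), `fcpinet`
computes:

* **Pigment census and stoichiometry** — per-class counts (Chl *a*, Chl *c*,
  fucoxanthin, diadinoxanthin, β-carotene), core/antenna split, and the
  standard ratios: antenna Chl *a*/*c* = (Chl *a*<sub>tot</sub> −
  Chl *a*<sub>core</sub>)/Chl *c*, mean Chl *c* per antenna, and
  Chl/Car = (antenna Chl *a* + Chl *c*)/(Fx + Ddx).
* **Membrane leaflets** — the membrane normal **n** is the smallest-eigenvalue
  eigenvector of the chlorophyll-Mg covariance matrix, oriented so a stromal
  landmark (by default the Fe₄S₄ cluster centroid) projects positive; a
  deterministic 1-D 2-means on the Mg projections places the midplane, and
  every chlorophyll is labelled stromal or lumenal.
* **Antenna layers** — a chain contact graph (heavy-atom pairs ≤ 4 Å) and
  breadth-first shells from the core subunits: shell 1 = innermost antenna
  ring, 2 = middle, 3 = outermost.
* **The Mg–Mg excitation-energy-transfer (EET) network** — coupled
  chlorophyll pairs (Mg–Mg ≤ 12 Å), directed inter-subunit steps (the
  minimal Chl *a* Mg–Mg distance per donor→acceptor pair and leaflet,
  within 26 Å; steps > 20 Å flagged less efficient), and pathway assembly:
  maximal chains per leaflet from source antennas down to a core subunit,
  encoded as `18-17-6-AL` (antenna numbers, core letter, S/L for
  stromal/lumenal).

A seeded synthetic-structure generator (`fcpinet.synth`) emits toy
supercomplexes with exact ground truth (leaflets, shells, step edges,
pathway codes, census), so the whole pipeline is testable without any
download.

## Worked example

Generate a toy supercomplex at the default paper-like scale (12 cores,
antenna rings of 11/10/3) and run the full pipeline:

```sh
fcpinet synth --seed 3 --out toy.cif --truth truth.json --chain-config-out chains.yaml
fcpinet all toy.cif --chain-config chains.yaml --step-cutoff 12 --out-dir run/
```

The JSON summary printed by the second command contains (abridged):

```
"census": {"totals": {"chl_a": 288, "chl_c": 24, "fucoxanthin": 96,
                      "beta_carotene": 48, ...}, ...},
"n_pathways": 11,
"pathway_codes": ["13-2-BS", "14-3-CS", ..., "24-19-9-MS"],
```

288 Chl *a* is 36 subunits × 8; the 11 pathway codes are the chains from
each source antenna (one with no incoming step) down to its core subunit,
all on the stromal side — and they match `truth.json` exactly.

The published step table ships as a flat edge list; assembling it yields
the published 18 pathway codes:

```sh
fcpinet pathways --from-edges src/fcpinet/data/table2_steps.tsv --json
# -> {"n_pathways": 18, "codes": ["1-IL", "11-BL", ..., "24-15-4-AL"]}
```

And the pure-arithmetic census mode reproduces the published stoichiometry
from the ligand counts alone:

```sh
fcpinet census --counts src/fcpinet/data/census_6ly5.yaml --json
# -> {"chl_a_to_c": 6.82, "avg_chl_c_per_antenna": 1.4,
#     "chl_to_car": 1.94, "total_pigments": 515}
```

## Library use

```python
import fcpinet as f

model = f.parse_structure("complex.cif", chain_config=f.load_chain_config("chains.yaml"))
frame = f.estimate_frame(model.pigments, f.stromal_reference_from_fes(model))
model = f.assign_leaflets(model, frame)
layers = f.assign_layers(f.build_contact_graph(model), model.chains)
steps = f.derive_eet_steps(model, layers)
paths = f.assemble_pathways(steps, model.annotations_by_label)
print(sorted(p.code for p in paths if p.complete))
```

See `docs/methods.md` for the model, parameter defaults, and limitations.
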