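# Methods

## Problem and model

Thylakoid pigment–protein supercomplexes such as the diatom PSI–FCPI bind
hundreds of chlorophylls and carotenoids whose spatial arrangement encodes
how absorbed excitation energy funnels from peripheral antennas to the
reaction center.  `fcpinet` treats this as a geometry problem on the
deposited coordinates: the proxy for excitonic connectivity between two
chlorophylls is the Euclidean distance between their central Mg atoms
("Mg–Mg distance"), and antenna topology is read off the protein contact
graph.  No excitonic couplings, Förster rates, or excitation dynamics are
computed — distances and discrete network structure only.

The pipeline runs in the order: parse → membrane frame → leaflets →
contact graph → layers → coupled pairs → EET steps → pathways → census.

## Pigment extraction

Coordinates are read with gemmi (mmCIF preferred, PDB v3.3 fallback).
Pigment residues are recognised by chemical-component code through an
editable class map; the packaged default uses PDB Chemical Component
Dictionary codes (CLA = Chl *a*, KC1/KC2 = Chl *c1*/*c2*, A86 =
fucoxanthin, DD6 = diadinoxanthin, BCR = β-carotene).  Component codes
vary across depositions, so the map is a config, not a constant.

Each chlorophyll is represented by its Mg position; a chlorophyll without
an Mg atom is an error in strict mode and a skipped record otherwise.
Carotenoids are represented by their unweighted heavy-atom centroid — they
enter leaflet/census reporting but never the distance network, which is
restricted to Chl *a* Mg atoms.  Alternate-location duplicates are resolved
by keeping the highest-occupancy conformer (first on ties), which makes
parsing deterministic.  Waters, lipids, detergents, quinones, and metal
clusters are parsed as atoms but are not pigments.

## Membrane frame and leaflets

Chlorophyll Mg atoms in a membrane complex lie in a slab that is wide in
the membrane plane and thin along the normal, in two layers (one per
leaflet).  The normal is therefore estimated as the eigenvector of the
Mg covariance matrix with the smallest eigenvalue.  The covariance normal
has no intrinsic sign, so a stromal landmark is required; by default the
centroid of Fe₄S₄ cluster atoms is used (the terminal electron acceptors
of PSI sit on the stromal side), otherwise the caller must supply a
reference point.

The midplane is found by a deterministic 1-D 2-means on the Mg
projections, initialised at the 25th/75th percentiles and iterated to
convergence; the midplane offset is the midpoint of the two cluster
centers.  Requirements and failure modes:

* fewer than 10 chlorophylls → insufficient-data error (a covariance
  plane fit on fewer points is meaningless);
* cluster centers closer than 5 Å → degenerate-leaflet error rather than
  an arbitrary split.  This also fires on nearly collinear complexes,
  where the "membrane plane" is not spanned by the pigment cloud;
* chlorophylls within 3 Å of the midplane keep their side assignment but
  are flagged `near_midplane`, since intermediate chlorophylls can
  genuinely straddle the leaflets; they are never silently forced.

Carotenoids inherit the leaflet of their nearest chlorophyll.  The frame
is equivariant under rigid motion by construction (tested to 1e-6).

## Antenna layers

Two chains are in contact when any heavy-atom pair is within 4.0 Å (the
conventional crystallographic contact criterion; exposed as a flag).  The
shell index of a subunit is its breadth-first distance from the set of
core subunits, expanded from all cores simultaneously: 0 = core,
1 = innermost antenna layer, 2 = middle, 3 = outermost.  Antennas
disconnected from the core get shell ∞ with a warning, not a failure, and
shells deeper than 3 are reported as-is with a warning.  Layers are
computed from protein contacts, not pigment distances, because layer
membership is a statement about protein attachment.

## Coupled pairs, steps, pathways

* **Coupled pairs**: all unordered chlorophyll pairs with Mg–Mg ≤ 12 Å
  (default; reported coupled pairs in such complexes run ≈ 9.5–11 Å, so
  12 Å brackets them with margin).  Pairs are stored canonically
  (lexicographic pigment ids) and annotated same-/cross-subunit; a pair
  straddling the midplane gets leaflet "mixed".
* **EET steps**: for each ordered subunit pair with strictly decreasing
  shell index (outer antenna → inner antenna, antenna → core) and each
  leaflet, the single minimal Chl *a* Mg–Mg distance is emitted as a
  directed step if ≤ 26 Å.  The 26 Å default brackets the longest step in
  the published pathway table (25.7 Å); the publication states no cutoff,
  so the value is a documented choice, exposed as a flag.  One step per
  (donor, acceptor, leaflet) triple mirrors how published pathway tables
  list exactly one pigment pair per subunit hop.  Steps longer than 20 Å
  are flagged "less efficient", following the distance criterion used to
  qualify long hops.
* **Pathways**: per leaflet the deduplicated steps form a directed graph,
  required to be acyclic (a cycle is an error naming the cycle).  Sources
  are subunits with outgoing but no incoming steps; pathways are all
  maximal simple chains from a source, followed until a core subunit.
  Branching sources yield one pathway per branch and chains converging on
  a shared inner hop count separately — this reproduces the published
  convention where two converging routes are listed as two pathways
  sharing a printed hop.  A chain dead-ending off-core is emitted with a
  warning flag and excluded from the headline count.  Codes are
  dash-joined donor antenna numbers, then the core subunit letter, then
  S/L for the leaflet.

De novo enumeration on a real structure is expected to yield a superset
of a published hand-curated pathway list, because such lists involve
judgment beyond pure geometry ("measuring, comparing and analyzing" is
not a reproducible selection rule).  The exact reproduction target is
therefore the packaged edge-list encoding of the published step table
(36 printed rows, 34 unique hops, 18 pathway groups), which the assembler
maps to exactly the 18 published codes; on the deposited structure the
published codes are checked to be a subset of the de novo enumeration.
The published text also names the four > 20 Å inner hops per leaflet in a
way that does not match the table's distances row by row; the package
hard-codes neither reading and reports per-step efficiency flags instead.

## Census and ratios

Counts are exact integers per pigment class, split core/antenna by chain
role.  Ratios: antenna Chl *a*/*c* = (Chl *a*ₜₒₜ − Chl *a*ᶜᵒʳᵉ)/Chl *c*;
mean Chl *c* per antenna = Chl *c*/n_antennas; Chl/Car =
(antenna Chl *a* + Chl *c*)/(Fx + Ddx).  The Chl/Car denominator includes
*all* fucoxanthins and diadinoxanthins, core-bound ones included — that is
the convention under which the published 1.94 is recovered from the
published counts (excluding the four core carotenoids does not give it).
Report fields are rounded half-up at the printed precision (2 d.p. for
ratios, 1 d.p. for the per-antenna average and for table distances); full
precision is kept internally.

## Synthetic generator

`fcpinet.synth.generate` emits a legal mmCIF whose defaults mirror the
layered supercomplex architecture: 12 core subunits clustered at an 8 Å
ring around the origin, three antenna rings of 11/10/3 subunits at 50 Å
ring spacing, 8 Chl *a* + 1 Chl *c* + 4 carotenoids per subunit,
chlorophylls split between leaflet planes 20 Å apart with 1 Å Gaussian
jitter (one seeded NumPy stream; a seed fixes every byte of the output).
Each antenna has a designated bridge Chl *a* pair (9 Å) toward its inward
neighbour placed on the inter-center line; the generator then verifies by
brute force that, at the recovery step cutoff of 12 Å, the minimal Chl *a*
pair for every downhill subunit pair is exactly the intended bridge with
≥ 2 Å margin and that no unintended pair qualifies — if the requested
geometry violates this, generation fails rather than emit an inconsistent
ground truth.  Inter-subunit "anchor" Cα pairs (3.5 Å) realise a declared
contact adjacency; the shipped ground-truth adjacency is recomputed from
the emitted coordinates, and the generator asserts the resulting BFS
shells equal the ring indices.  An Fe₄S₄ residue above the stromal plane
provides the default orientation landmark.

What the toy does *not* emulate: real protein backbones, pigment
chemistry (a synthetic chlorophyll is an Mg atom plus four N
placeholders), tilted or curved membranes, mixed-leaflet interface
pigments, and the irregular spacing of real antenna rings.  Passing the
recovery tests therefore demonstrates correctness of the geometric logic
(leaflet split, BFS shells, minimal-step selection, chain assembly), not
robustness to the full messiness of experimental models — the latter is
what the deposited-structure checks cover when the deposition is
available.

## Problem sizes and numerics

The test suite runs on generated models of 456 pigments (default scale)
and smaller; the acceptance script uses the in-paper census counts, the
36-row step table, and one default-scale synthetic self-check — everything
completes in seconds.  Distance comparisons against printed values use
half-up rounding to 0.1 Å.  Ties in the altloc choice, 2-means
initialisation, and chain enumeration order are all resolved
deterministically, so fixed inputs give byte-identical outputs (summaries
contain no timestamps).

## Known limitations

* The chain → subunit config for the deposited diatom model is shipped as
  a template: the publication fixes only PsaR = chain h and PsaS = chain g,
  and the FCPI-1…24 numbering is the publication's, not the file's; the
  antenna entries must be completed against the deposition before
  structure-specific pathway codes can be reproduced verbatim.
* Leaflet assignment assumes a planar membrane; strongly curved or tilted
  two-leaflet geometries beyond a single plane fit are out of scope.
* No interface-area, hydrogen-bond, or interaction-chemistry analysis;
  no spectra, couplings, or rates.
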