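"""Synthetic supercomplex generator with exact ground truth.

Emits a legal mmCIF of a toy pigment-protein supercomplex whose geometry
mimics a photosystem-I/antenna assembly: a tight cluster of core subunits
at the origin surrounded by concentric antenna rings (default ring sizes
11/10/3 antennas, matching the layered organisation of a diatom PSI-FCPI
supercomplex), chlorophylls split between two leaflet planes, carotenoid
rods, iron-sulfur clusters as the stromal landmark, and inter-subunit
"anchor" contacts that realise a known adjacency.

Designated bridge chlorophylls are placed so that each antenna has exactly
one intended minimal Chl-a step toward its inward neighbour, unique by a
>= 2 Angstrom margin at the recovery step cutoff; the generator verifies
this against a brute-force all-pairs search before returning, so the
:class:`GroundTruth` (shells, leaflets, step edges, pathway codes, census)
is guaranteed self-consistent with the emitted coordinates.

No chemistry is claimed: a synthetic chlorophyll is an Mg atom plus four
N placeholders, a carotenoid a short carbon rod.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import gemmi
import numpy as np

from .exceptions import ConfigError
from .network import EETStep, read_edge_list
from .structure_io import Leaflet

#: Core subunit letters in the 12-subunit convention (PsaA..PsaM, PsaR, PsaS).
CORE_LETTERS = "ABCDEFIJLMRS"
_EXTRA_LETTERS = "GHKNOPQTUVWXYZ"

#: Geometry constants (Angstrom).
CORE_RING_RADIUS = 8.0
CORE_CHL_LOCAL_RADIUS = 2.0
ANTENNA_CHL_LOCAL_RADIUS = 5.0
BRIDGE_DISTANCE = 9.0
ANCHOR_SEPARATION = 3.5
#: Step cutoff under which recovery of the intended steps is exact.
RECOVERY_STEP_CUTOFF = 12.0
#: Margin by which intended bridges beat any competing cross-subunit pair.
BRIDGE_MARGIN = 2.0

# Component codes drawn from the packaged default class map.
CODE_CHL_A = "CLA"
CODE_CHL_C = "KC2"
CODE_FX = "A86"
CODE_BCR = "BCR"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the toy supercomplex.

    Defaults emulate the layered diatom PSI-FCPI organisation: 12 core
    subunits, three antenna rings of 11/10/3 subunits at 50 Angstrom ring
    spacing, 8 Chl a + 1 Chl c + 4 carotenoids per subunit, leaflet planes
    20 Angstrom apart with 1 Angstrom positional jitter.
    """

    n_core_subunits: int = 12
    n_rings: int = 3
    antennas_per_ring: Union[int, tuple[int, ...]] = (11, 10, 3)
    chl_a_per_subunit: int = 8
    chl_c_per_subunit: int = 1
    car_per_subunit: int = 4
    leaflet_gap: float = 20.0
    ring_spacing: float = 50.0
    jitter_sd: float = 1.0
    seed: int = 0

    def ring_sizes(self) -> tuple[int, ...]:
        if isinstance(self.antennas_per_ring, int):
            return (self.antennas_per_ring,) * self.n_rings
        return tuple(self.antennas_per_ring)

    def validate(self) -> None:
        if self.n_core_subunits < 1:
            raise ConfigError("need at least one core subunit")
        if self.n_rings < 0:
            raise ConfigError("n_rings must be non-negative")
        sizes = self.ring_sizes()
        if len(sizes) != self.n_rings:
            raise ConfigError(
                f"antennas_per_ring has {len(sizes)} entries for {self.n_rings} rings")
        if any(m < 1 for m in sizes) and self.n_rings > 0:
            raise ConfigError("each ring must hold at least one antenna")
        for name in ("chl_a_per_subunit", "chl_c_per_subunit", "car_per_subunit"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_rings > 0 and self.chl_a_per_subunit < 1:
            raise ConfigError("antenna rings need chl_a_per_subunit >= 1 for bridges")
        if self.leaflet_gap < 2 * self.jitter_sd + 6:
            raise ConfigError(
                f"leaflet_gap ({self.leaflet_gap}) must be >= 2*jitter_sd + 6 "
                f"({2 * self.jitter_sd + 6}) to keep leaflets separable")
        if self.ring_spacing < 30:
            raise ConfigError("ring_spacing below 30 A breaks bridge uniqueness")


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from the generated file."""

    chain_labels: dict[str, str]          # chain id -> subunit label
    shells: dict[str, int]                # subunit label -> shell index
    chl_leaflets: dict[str, str]          # "chain:resnum" -> stromal/lumenal
    pigment_leaflets: dict[str, str]      # all pigments, same keying
    step_edges: list[dict]                # intended minimal steps
    pathway_codes: list[str]
    census: dict[str, int]
    adjacency: list[list[str]]            # contact pairs (subunit labels)
    step_cutoff: float
    stromal_reference: list[float]
    spec: dict

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))

    def steps(self) -> list[EETStep]:
        return [EETStep(donor_subunit=e["donor_subunit"],
                        acceptor_subunit=e["acceptor_subunit"],
                        donor_site=e["donor_site"],
                        acceptor_site=e["acceptor_site"],
                        distance=e["distance"],
                        leaflet=Leaflet(e["leaflet"]))
                for e in self.step_edges]


def _core_label(i: int) -> str:
    letters = CORE_LETTERS + _EXTRA_LETTERS
    return f"Psa{letters[i]}"


def _round3(v: Sequence[float]) -> np.ndarray:
    # emitted coordinates are pre-rounded to the mmCIF precision so that a
    # parse round trip is exact
    return np.round(np.asarray(v, dtype=float), 3)


class _Pigment:
    __slots__ = ("chain", "resnum", "code", "pos", "leaflet", "label")

    def __init__(self, chain, resnum, code, pos, leaflet, label):
        self.chain = chain
        self.resnum = resnum
        self.code = code
        self.pos = _round3(pos)
        self.leaflet = leaflet
        self.label = label


def generate(spec: SyntheticSpec,
             out_path: Optional[Union[str, Path]] = None,
             ) -> tuple[str, GroundTruth]:
    """Build the toy supercomplex; return (mmCIF text, ground truth).

    Raises :class:`ConfigError` on an invalid spec before writing anything.
    The same seed always yields byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = spec.ring_sizes()
    gap = spec.leaflet_gap

    # --- subunit centers -------------------------------------------------
    # label -> (chain_id, center xy, shell)
    centers: dict[str, np.ndarray] = {}
    chain_of: dict[str, str] = {}
    shells: dict[str, int] = {}
    core_labels = [_core_label(i) for i in range(spec.n_core_subunits)]
    for i, label in enumerate(core_labels):
        ang = 2 * math.pi * i / spec.n_core_subunits
        centers[label] = np.array([CORE_RING_RADIUS * math.cos(ang),
                                   CORE_RING_RADIUS * math.sin(ang)])
        chain_of[label] = f"c{i + 1}"
        shells[label] = 0
    antenna_labels_by_ring: list[list[str]] = []
    n_ant = 0
    for k, m in enumerate(sizes, start=1):
        ring = []
        for j in range(m):
            n_ant += 1
            label = f"FCPI-{n_ant}"
            ang = 2 * math.pi * j / m + 0.05 * k
            centers[label] = np.array([k * spec.ring_spacing * math.cos(ang),
                                       k * spec.ring_spacing * math.sin(ang)])
            chain_of[label] = f"f{n_ant}"
            shells[label] = k
        antenna_labels_by_ring.append(
            [f"FCPI-{n}" for n in range(n_ant - m + 1, n_ant + 1)])

    def angle(label: str) -> float:
        c = centers[label]
        return math.atan2(c[1], c[0])

    def nearest_by_angle(label: str, candidates: list[str]) -> str:
        a = angle(label)
        return min(candidates,
                   key=lambda t: (abs(((angle(t) - a + math.pi) % (2 * math.pi))
                                      - math.pi), t))

    # inward target of every antenna
    target: dict[str, str] = {}
    for k, ring in enumerate(antenna_labels_by_ring):
        inner = core_labels if k == 0 else antenna_labels_by_ring[k - 1]
        for label in ring:
            target[label] = nearest_by_angle(label, inner)
    incoming: dict[str, list[str]] = {}
    for s, t in target.items():
        incoming.setdefault(t, []).append(s)
    for t, sources_in in incoming.items():
        reserved = 0 if shells[t] == 0 else 1  # antennas keep index 0 as donor
        if reserved + len(sources_in) > spec.chl_a_per_subunit:
            raise ConfigError(
                f"subunit {t} receives {len(sources_in)} bridges but has only "
                f"{spec.chl_a_per_subunit} Chl a; raise chl_a_per_subunit")

    # --- pigments --------------------------------------------------------
    pigments: list[_Pigment] = []
    chl_index: dict[tuple[str, int], _Pigment] = {}

    for label in core_labels + [a for ring in antenna_labels_by_ring for a in ring]:
        cx, cy = centers[label]
        is_core = shells[label] == 0
        local_r = CORE_CHL_LOCAL_RADIUS if is_core else ANTENNA_CHL_LOCAL_RADIUS
        n_a = spec.chl_a_per_subunit
        for i in range(n_a):
            ang = 2 * math.pi * i / max(n_a, 1)
            stromal = i % 2 == 0
            z = gap if stromal else 0.0
            pos = np.array([cx + local_r * math.cos(ang),
                            cy + local_r * math.sin(ang), z])
            pos = pos + rng.normal(0.0, spec.jitter_sd, size=3)
            resnum = (801 + i) if is_core else (400 + i)
            p = _Pigment(chain_of[label], resnum, CODE_CHL_A, pos,
                         Leaflet.STROMAL if stromal else Leaflet.LUMENAL, label)
            pigments.append(p)
            chl_index[(label, i)] = p
        if not is_core:
            for i in range(spec.chl_c_per_subunit):
                ang = 2 * math.pi * (i + 0.5) / max(spec.chl_c_per_subunit, 1)
                pos = np.array([cx + (local_r + 2.0) * math.cos(ang),
                                cy + (local_r + 2.0) * math.sin(ang), gap])
                pos = pos + rng.normal(0.0, spec.jitter_sd, size=3)
                pigments.append(_Pigment(chain_of[label], 400 + n_a + i,
                                         CODE_CHL_C, pos, Leaflet.STROMAL, label))
        car_code = CODE_BCR if is_core else CODE_FX
        for i in range(spec.car_per_subunit):
            ang = 2 * math.pi * (i + 0.25) / max(spec.car_per_subunit, 1)
            stromal = i % 2 == 0
            z = gap - 2.0 if stromal else 2.0
            pos = np.array([cx + (local_r + 1.0) * math.cos(ang),
                            cy + (local_r + 1.0) * math.sin(ang), z])
            pigments.append(_Pigment(chain_of[label], 301 + i, car_code,
                                     pos, Leaflet.STROMAL if stromal else
                                     Leaflet.LUMENAL, label))

    # --- bridges: reposition designated Chls a onto radial lines ---------
    acceptor_slot: dict[str, int] = {}
    step_edges: list[dict] = []
    for ring in antenna_labels_by_ring:
        for s in ring:
            t = target[s]
            cs = np.append(centers[s], 0.0)
            ct = np.append(centers[t], 0.0)
            u = (cs - ct)
            u = u / np.linalg.norm(u)
            mid = (cs + ct) / 2.0
            donor_pos = mid + u * (BRIDGE_DISTANCE / 2.0)
            acceptor_pos = mid - u * (BRIDGE_DISTANCE / 2.0)
            donor_pos[2] = acceptor_pos[2] = gap  # stromal plane
            donor = chl_index[(s, 0)]
            slot = acceptor_slot.get(t, 0)
            acceptor_slot[t] = slot + 1
            acceptor = chl_index[(t, slot if shells[t] == 0 else slot + 1)]
            donor.pos = _round3(donor_pos)
            donor.leaflet = Leaflet.STROMAL
            acceptor.pos = _round3(acceptor_pos)
            acceptor.leaflet = Leaflet.STROMAL
            step_edges.append({
                "donor_subunit": s, "acceptor_subunit": t,
                "donor_site": donor.resnum, "acceptor_site": acceptor.resnum,
                "distance": float(np.linalg.norm(donor.pos - acceptor.pos)),
                "leaflet": Leaflet.STROMAL.value,
            })

    # --- verify uniqueness/margin of intended steps by brute force -------
    _verify_steps(pigments, shells, step_edges)

    # --- pathways implied by the bridges ---------------------------------
    targeted = set(target.values())
    sources = sorted((s for s in target if s not in targeted),
                     key=lambda s: int(s.split("-")[1]))
    pathway_codes = []
    for src in sources:
        chain, node = [], src
        while shells[node] > 0:
            chain.append(node)
            node = target[node]
        numbers = [lbl.split("-")[1] for lbl in chain]
        pathway_codes.append("-".join(numbers) + "-" + node[3] + "S")

    # --- protein anchors realising the declared adjacency ----------------
    adjacency_pairs: list[tuple[str, str]] = []
    for i in range(spec.n_core_subunits):
        if spec.n_core_subunits > 1:
            a = core_labels[i]
            b = core_labels[(i + 1) % spec.n_core_subunits]
            if a != b and tuple(sorted((a, b))) not in adjacency_pairs:
                adjacency_pairs.append(tuple(sorted((a, b))))
    for s, t in sorted(target.items()):
        adjacency_pairs.append(tuple(sorted((s, t))))

    anchors: dict[str, list[np.ndarray]] = {}
    for a, b in adjacency_pairs:
        ca = np.append(centers[a], gap / 2.0)
        cb = np.append(centers[b], gap / 2.0)
        u = cb - ca
        norm = np.linalg.norm(u)
        u = u / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        mid = (ca + cb) / 2.0
        anchors.setdefault(a, []).append(_round3(mid - u * (ANCHOR_SEPARATION / 2)))
        anchors.setdefault(b, []).append(_round3(mid + u * (ANCHOR_SEPARATION / 2)))

    # --- true adjacency from the emitted coordinates ---------------------
    adjacency = _contact_pairs(pigments, anchors, chain_of, cutoff=4.0)
    truth_shells = _bfs_shells(adjacency, core_labels, shells)
    if truth_shells != shells:
        raise ConfigError("synthetic geometry produced unintended contacts; "
                          "shell structure is not the declared ring structure")

    # --- stromal landmark -------------------------------------------------
    fes_center = np.array([0.0, 0.0, gap + 15.0])

    # --- census -----------------------------------------------------------
    n_core = spec.n_core_subunits
    census = {
        "chl_a": (n_core + n_ant) * spec.chl_a_per_subunit,
        "chl_c": n_ant * spec.chl_c_per_subunit,
        "fucoxanthin": n_ant * spec.car_per_subunit,
        "diadinoxanthin": 0,
        "beta_carotene": n_core * spec.car_per_subunit,
    }

    cif_text = _write_cif(spec, pigments, anchors, chain_of, fes_center)
    if out_path is not None:
        Path(out_path).write_text(cif_text)

    chl_leaflets = {f"{p.chain}:{p.resnum}": p.leaflet.value
                    for p in pigments if p.code in (CODE_CHL_A, CODE_CHL_C)}
    pigment_leaflets = dict(chl_leaflets)
    # carotenoid leaflet := nearest chlorophyll's, from the final coordinates
    chls = [p for p in pigments if p.code in (CODE_CHL_A, CODE_CHL_C)]
    chl_pts = np.array([p.pos for p in chls])
    for p in pigments:
        if p.code in (CODE_CHL_A, CODE_CHL_C):
            continue
        d = np.linalg.norm(chl_pts - p.pos, axis=1)
        pigment_leaflets[f"{p.chain}:{p.resnum}"] = chls[int(np.argmin(d))].leaflet.value

    truth = GroundTruth(
        chain_labels={chain_of[lbl]: lbl for lbl in chain_of},
        shells=shells,
        chl_leaflets=chl_leaflets,
        pigment_leaflets=pigment_leaflets,
        step_edges=step_edges,
        pathway_codes=pathway_codes,
        census=census,
        adjacency=[list(p) for p in sorted(adjacency)],
        step_cutoff=RECOVERY_STEP_CUTOFF,
        stromal_reference=[float(c) for c in fes_center],
        spec=asdict(spec),
    )
    return cif_text, truth


def _verify_steps(pigments: list[_Pigment], shells: dict[str, int],
                  step_edges: list[dict]) -> None:
    """Brute-force check: at the recovery cutoff, the minimal Chl-a pair per
    downhill subunit pair is exactly the intended bridge, with margin."""
    chl_a = [p for p in pigments if p.code == CODE_CHL_A]
    intended = {(e["donor_subunit"], e["acceptor_subunit"], e["leaflet"]): e
                for e in step_edges}
    # two smallest distances per (donor subunit, acceptor subunit, leaflet)
    best: dict[tuple[str, str, str], tuple[float, int, int]] = {}
    second: dict[tuple[str, str, str], float] = {}
    for p in chl_a:
        for q in chl_a:
            if p.label == q.label or shells[p.label] <= shells[q.label]:
                continue
            if p.leaflet is not q.leaflet:
                continue
            d = float(np.linalg.norm(p.pos - q.pos))
            key = (p.label, q.label, p.leaflet.value)
            if key not in best or d < best[key][0]:
                if key in best:
                    second[key] = min(second.get(key, math.inf), best[key][0])
                best[key] = (d, p.resnum, q.resnum)
            else:
                second[key] = min(second.get(key, math.inf), d)
    derived = {k: v for k, v in best.items() if v[0] <= RECOVERY_STEP_CUTOFF}
    if set(derived) != set(intended):
        raise ConfigError(
            f"bridge construction failed: derived step pairs {sorted(derived)} "
            f"!= intended {sorted(intended)}")
    for key, (d, dn, an) in derived.items():
        e = intended[key]
        if (dn, an) != (e["donor_site"], e["acceptor_site"]):
            raise ConfigError(f"step {key}: minimal pair is not the bridge pair")
        if d > RECOVERY_STEP_CUTOFF - BRIDGE_MARGIN:
            raise ConfigError(f"step {key}: bridge distance {d:.1f} too close "
                              f"to the recovery cutoff")
        if second.get(key, math.inf) < d + BRIDGE_MARGIN:
            raise ConfigError(f"step {key}: competing pair within "
                              f"{BRIDGE_MARGIN} A of the bridge pair")


def _contact_pairs(pigments: list[_Pigment], anchors: dict[str, list[np.ndarray]],
                   chain_of: dict[str, str], cutoff: float) -> set[tuple[str, str]]:
    by_label: dict[str, list[np.ndarray]] = {}
    for p in pigments:
        by_label.setdefault(p.label, []).append(p.pos)
    for label, pts in anchors.items():
        by_label.setdefault(label, []).extend(pts)
    labels = sorted(by_label)
    arrays = {k: np.array(v) for k, v in by_label.items()}
    pairs: set[tuple[str, str]] = set()
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = np.linalg.norm(arrays[a][:, None, :] - arrays[b][None, :, :], axis=2)
            if d.min() <= cutoff:
                pairs.add((a, b))
    return pairs


def _bfs_shells(adjacency: set[tuple[str, str]], core_labels: list[str],
                all_labels: dict[str, int]) -> dict[str, int]:
    from collections import deque

    neighbors: dict[str, set[str]] = {k: set() for k in all_labels}
    for a, b in adjacency:
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    dist = {c: 0 for c in core_labels}
    queue = deque(core_labels)
    while queue:
        u = queue.popleft()
        for v in neighbors.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return {k: dist.get(k, -1) for k in all_labels}


# ---------------------------------------------------------------------------
# mmCIF emission
# ---------------------------------------------------------------------------

_CHL_ATOMS = [("MG", "Mg"), ("NA", "N"), ("NB", "N"), ("NC", "N"), ("ND", "N")]
_CAR_ROD = 5  # carbon atoms per carotenoid rod


def _write_cif(spec: SyntheticSpec, pigments: list[_Pigment],
               anchors: dict[str, list[np.ndarray]],
               chain_of: dict[str, str], fes_center: np.ndarray) -> str:
    st = gemmi.Structure()
    st.name = "synthetic supercomplex"
    model = gemmi.Model("1")

    chains: dict[str, gemmi.Chain] = {}

    def chain(cid: str) -> gemmi.Chain:
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        return chains[cid]

    def add_residue(cid: str, name: str, seqid: int,
                    atoms: list[tuple[str, str, np.ndarray]]) -> None:
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(seqid, " ")
        res.het_flag = "H" if name != "GLY" else "A"
        for aname, elem, pos in atoms:
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
        chain(cid).add_residue(res)

    # anchors first so chains hold protein-esque residues too
    anchor_seq: dict[str, int] = {}
    for label in sorted(anchors):
        cid = chain_of[label]
        for pos in anchors[label]:
            anchor_seq[cid] = anchor_seq.get(cid, 0) + 1
            add_residue(cid, "GLY", anchor_seq[cid], [("CA", "C", pos)])

    for p in sorted(pigments, key=lambda p: (p.chain, p.resnum)):
        if p.code in (CODE_CHL_A, CODE_CHL_C):
            atoms = [("MG", "Mg", p.pos)]
            for i, (aname, elem) in enumerate(_CHL_ATOMS[1:]):
                offset = np.zeros(3)
                offset[i % 2] = 2.1 if i < 2 else -2.1
                atoms.append((aname, elem, _round3(p.pos + offset)))
            add_residue(p.chain, p.code, p.resnum, atoms)
        else:
            atoms = []
            for i in range(_CAR_ROD):
                pos = p.pos + np.array([1.4 * (i - (_CAR_ROD - 1) / 2), 0.0, 0.0])
                atoms.append((f"C{i + 1}", "C", _round3(pos)))
            add_residue(p.chain, p.code, p.resnum, atoms)

    # Fe4S4 stromal landmark on the first core chain
    fes_atoms = []
    for i, offset in enumerate([(1.1, 0, 0), (-1.1, 0, 0), (0, 1.1, 0), (0, -1.1, 0)]):
        fes_atoms.append((f"FE{i + 1}", "Fe", _round3(fes_center + np.array(offset))))
    add_residue("c1", "SF4", 901, fes_atoms)

    for cid in sorted(chains):
        model.add_chain(chains[cid])
    st.add_model(model)
    st.setup_entities()
    doc = st.make_mmcif_document()
    return doc.as_string()


# ---------------------------------------------------------------------------
# Packaged literal encoding of the published step table
# ---------------------------------------------------------------------------


def table2_fixture_path() -> Path:
    """Path of the packaged published-step-table edge list (TSV)."""
    from importlib.resources import files

    return Path(str(files("fcpinet").joinpath("data/table2_steps.tsv")))


def table2_fixture() -> list[EETStep]:
    """The packaged published step table as a flat edge list.

    One row per printed step line (36 rows across 18 pathway groups; two
    hops shared between converging pathways appear twice, exactly as
    printed).
    """
    return read_edge_list(table2_fixture_path())
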