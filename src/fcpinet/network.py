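"""Chlorophyll Mg-Mg distance network: coupled pairs, inter-subunit
excitation-energy-transfer (EET) steps, and pathway assembly.

The excitation-transfer proxy is the Euclidean distance between the
central Mg atoms of two chlorophylls.  Within a subunit, chlorophyll pairs
closer than ``pair_cutoff`` (default 12 Angstrom) are "coupled pairs" that
can act as red-shifted excitation traps.  Between subunits, a directed EET
step runs from a higher antenna shell toward a lower one (outer antenna ->
inner antenna -> core), taking the single minimal Chl-a Mg-Mg distance per
(donor, acceptor, leaflet) triple within ``step_cutoff`` (default 26
Angstrom).  Steps longer than 20 Angstrom are flagged as less efficient.

Per leaflet the steps form a directed acyclic graph; a pathway is a
maximal simple chain from a source subunit (outgoing steps, no incoming)
to a core subunit, encoded as dash-joined antenna numbers followed by the
core subunit letter and the leaflet letter, e.g. ``18-17-6-AL`` =
FCPI-18 -> FCPI-17 -> FCPI-6 -> PsaA, lumenal.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import AnalysisError, ConfigError, CycleError, ParameterError
from .layers import LayerAssignment
from .structure_io import (
    CHLOROPHYLL_CLASSES,
    Leaflet,
    PigmentClass,
    PigmentRecord,
    Role,
    StructureModel,
)

logger = logging.getLogger(__name__)

DEFAULT_STEP_CUTOFF = 26.0
DEFAULT_PAIR_CUTOFF = 12.0
#: Mg-Mg distance above which a step is considered less efficient.
EFFICIENCY_CUTOFF = 20.0

_CORE_RE = re.compile(r"^Psa([A-Z])$")
_ANTENNA_RE = re.compile(r"^FCPI-(\d+)$")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def mg_mg_distance(p: PigmentRecord, q: PigmentRecord) -> float:
    """Euclidean Mg-Mg distance between two chlorophylls (Angstrom)."""
    for r in (p, q):
        if not r.is_chlorophyll:
            raise TypeError(f"Mg-Mg distance requires chlorophylls; "
                            f"{r.pigment_id} is {r.pigment_class.value}")
    return float(np.linalg.norm(p.representative_point - q.representative_point))


# ---------------------------------------------------------------------------
# Coupled pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoupledPair:
    """Unordered chlorophyll pair within the coupling cutoff.

    Stored canonically with ``pigment_a`` the lexicographically smaller id.
    ``leaflet`` is the shared leaflet, or ``None`` if the two chlorophylls
    straddle the midplane.
    """

    pigment_a: tuple[str, int]
    pigment_b: tuple[str, int]
    distance: float
    leaflet: Optional[Leaflet]
    same_subunit: bool
    subunit_a: str = ""
    subunit_b: str = ""
    site_a: Optional[int] = None
    site_b: Optional[int] = None


def find_coupled_pairs(model: StructureModel,
                       pair_cutoff: float = DEFAULT_PAIR_CUTOFF,
                       classes: Iterable[PigmentClass] = CHLOROPHYLL_CLASSES,
                       ) -> list[CoupledPair]:
    """All unordered chlorophyll pairs with Mg-Mg distance <= ``pair_cutoff``.

    Restricted to the given pigment classes (default: both chlorophyll
    species).  The result is sorted by canonical pigment ids, so it is
    deterministic and input-order independent.
    """
    if pair_cutoff <= 0:
        raise ParameterError(f"pair_cutoff must be positive, got {pair_cutoff}")
    classes = set(classes)
    chls = [p for p in model.pigments if p.pigment_class in classes]
    if len(chls) < 2:
        return []
    points = np.array([p.representative_point for p in chls])
    tree = cKDTree(points)
    out: list[CoupledPair] = []
    for i, j in tree.query_pairs(r=pair_cutoff):
        p, q = chls[i], chls[j]
        if q.pigment_id < p.pigment_id:
            p, q = q, p
        leaflet = p.leaflet if p.leaflet is q.leaflet else None
        out.append(CoupledPair(
            pigment_a=p.pigment_id, pigment_b=q.pigment_id,
            distance=mg_mg_distance(p, q),
            leaflet=leaflet,
            same_subunit=p.subunit_label == q.subunit_label,
            subunit_a=p.subunit_label, subunit_b=q.subunit_label,
            site_a=p.site_number, site_b=q.site_number,
        ))
    out.sort(key=lambda c: (c.pigment_a, c.pigment_b))
    return out


# ---------------------------------------------------------------------------
# EET steps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EETStep:
    """Directed minimal Chl-a hop from a donor subunit to an acceptor.

    ``donor_site``/``acceptor_site`` carry the author residue numbers of
    the two chlorophylls; ``efficient`` is the <= 20 Angstrom criterion.
    """

    donor_subunit: str
    acceptor_subunit: str
    donor_site: int
    acceptor_site: int
    distance: float
    leaflet: Leaflet
    donor_pigment: Optional[tuple[str, int]] = None
    acceptor_pigment: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise AnalysisError(
                f"step {self.donor_subunit}->{self.acceptor_subunit} has "
                f"non-positive distance {self.distance}")

    @property
    def efficient(self) -> bool:
        return self.distance <= EFFICIENCY_CUTOFF


def _subunit_roles(labels: Iterable[str],
                   annotations: Optional[Mapping[str, "object"]] = None,
                   ) -> dict[str, tuple[Role, Optional[str], Optional[int]]]:
    """Resolve (role, core_letter, antenna_number) per subunit label.

    Uses explicit annotations when given, else the conventional label
    grammar (Psa[A-Z] -> core, FCPI-n -> antenna).
    """
    out: dict[str, tuple[Role, Optional[str], Optional[int]]] = {}
    for label in labels:
        ann = annotations.get(label) if annotations else None
        if ann is not None:
            out[label] = (ann.role, ann.core_letter, ann.antenna_number)
            continue
        m = _CORE_RE.match(label)
        if m:
            out[label] = (Role.CORE, m.group(1), None)
            continue
        m = _ANTENNA_RE.match(label)
        if m:
            out[label] = (Role.ANTENNA, None, int(m.group(1)))
            continue
        out[label] = (Role.OTHER, None, None)
    return out


def derive_eet_steps(model: StructureModel, layers: LayerAssignment,
                     step_cutoff: float = DEFAULT_STEP_CUTOFF) -> list[EETStep]:
    """Minimal Chl-a Mg-Mg step per (donor, acceptor, leaflet) triple.

    A step runs from a subunit of strictly higher shell index to one of
    lower index (outer antenna -> inner antenna or antenna -> core) and is
    emitted only if the minimal distance is within ``step_cutoff``.
    Only chlorophyll a participates; leaflets must be assigned.
    """
    if step_cutoff <= 0:
        raise ParameterError(f"step_cutoff must be positive, got {step_cutoff}")
    by_subunit_leaflet: dict[tuple[str, Leaflet], list[PigmentRecord]] = {}
    for p in model.pigments:
        if p.pigment_class is not PigmentClass.CHL_A:
            continue
        if p.leaflet is None:
            raise AnalysisError(f"chlorophyll {p.pigment_id} has no leaflet; "
                                f"run leaflet assignment first")
        by_subunit_leaflet.setdefault((p.subunit_label, p.leaflet), []).append(p)

    subunits = sorted({s for s, _ in by_subunit_leaflet})
    steps: list[EETStep] = []
    for donor_sub in subunits:
        d_shell = layers.shells.get(donor_sub)
        if d_shell is None or d_shell < 1 or math.isinf(d_shell):
            continue
        for acceptor_sub in subunits:
            a_shell = layers.shells.get(acceptor_sub)
            if a_shell is None or math.isinf(a_shell) or not d_shell > a_shell:
                continue
            for leaflet in (Leaflet.STROMAL, Leaflet.LUMENAL):
                donors = by_subunit_leaflet.get((donor_sub, leaflet), [])
                acceptors = by_subunit_leaflet.get((acceptor_sub, leaflet), [])
                if not donors or not acceptors:
                    continue
                dmat = np.linalg.norm(
                    np.array([p.representative_point for p in donors])[:, None, :]
                    - np.array([q.representative_point for q in acceptors])[None, :, :],
                    axis=2)
                i, j = np.unravel_index(int(np.argmin(dmat)), dmat.shape)
                dist = float(dmat[i, j])
                if dist <= step_cutoff:
                    steps.append(EETStep(
                        donor_subunit=donor_sub, acceptor_subunit=acceptor_sub,
                        donor_site=donors[i].residue_number,
                        acceptor_site=acceptors[j].residue_number,
                        distance=dist, leaflet=leaflet,
                        donor_pigment=donors[i].pigment_id,
                        acceptor_pigment=acceptors[j].pigment_id,
                    ))
    steps.sort(key=lambda s: (s.leaflet.value, s.donor_subunit, s.acceptor_subunit))
    return steps


# ---------------------------------------------------------------------------
# Pathway assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pathway:
    """Ordered chain of EET steps ending (normally) at a core subunit."""

    steps: tuple[EETStep, ...]
    leaflet: Leaflet
    terminal_core_letter: Optional[str]
    code: str
    complete: bool = True  # False when the chain dead-ends off-core

    @property
    def subunits(self) -> list[str]:
        return [self.steps[0].donor_subunit] + [s.acceptor_subunit for s in self.steps]


def pathway_code(steps: Sequence[EETStep],
                 roles: Mapping[str, tuple[Role, Optional[str], Optional[int]]],
                 ) -> str:
    """Canonical code: donor antenna numbers, core letter, leaflet letter."""
    if not steps:
        raise AnalysisError("cannot encode an empty pathway")
    numbers = []
    for s in steps:
        role, _, number = roles[s.donor_subunit]
        if number is None:
            raise ConfigError(f"donor subunit {s.donor_subunit} has no antenna number")
        numbers.append(str(number))
    terminal = steps[-1].acceptor_subunit
    role, letter, _ = roles[terminal]
    if role is not Role.CORE or letter is None:
        raise ConfigError(f"terminal subunit {terminal} has no core letter")
    leaflet_letter = "S" if steps[0].leaflet is Leaflet.STROMAL else "L"
    return "-".join(numbers) + "-" + letter + leaflet_letter


def assemble_pathways(steps: Iterable[EETStep],
                      annotations: Optional[Mapping[str, "object"]] = None,
                      ) -> list[Pathway]:
    """Enumerate maximal chains per leaflet from the step collection.

    Per leaflet: sources are subunits with at least one outgoing step and
    no incoming step; pathways are all maximal simple chains from a source,
    following steps until a core subunit is reached (branching sources
    yield one pathway per branch; chains converging on a shared inner step
    each count separately).  Identical duplicate steps (the same hop listed
    under two pathways) are merged; for the same (donor, acceptor, leaflet)
    triple the minimal-distance step is kept.  A cycle raises
    :class:`CycleError`; a chain dead-ending off-core is emitted with
    ``complete=False`` (excluded from the headline count) and a warning.
    """
    steps = list(steps)
    labels = {s.donor_subunit for s in steps} | {s.acceptor_subunit for s in steps}
    roles = _subunit_roles(labels, annotations)

    pathways: list[Pathway] = []
    for leaflet in (Leaflet.STROMAL, Leaflet.LUMENAL):
        edge_for: dict[tuple[str, str], EETStep] = {}
        for s in steps:
            if s.leaflet is not leaflet:
                continue
            key = (s.donor_subunit, s.acceptor_subunit)
            if key not in edge_for or s.distance < edge_for[key].distance:
                edge_for[key] = s
        if not edge_for:
            continue
        g = nx.DiGraph()
        for (u, v), s in edge_for.items():
            g.add_edge(u, v, step=s)
        if not nx.is_directed_acyclic_graph(g):
            cycle = " -> ".join(u for u, _ in nx.find_cycle(g))
            raise CycleError(f"step graph has a cycle on the {leaflet.value} side: "
                             f"{cycle}")
        sources = sorted(n for n in g.nodes
                         if g.out_degree(n) > 0 and g.in_degree(n) == 0)

        def extend(chain: list[EETStep]) -> None:
            tip = chain[-1].acceptor_subunit
            if roles[tip][0] is Role.CORE or g.out_degree(tip) == 0:
                complete = roles[tip][0] is Role.CORE
                if complete:
                    code = pathway_code(chain, roles)
                    letter = roles[tip][1]
                else:
                    logger.warning("chain %s ends at non-core subunit %s",
                                   [s.donor_subunit for s in chain] + [tip], tip)
                    code = "-".join(str(roles[s.donor_subunit][2]) for s in chain) \
                        + "-?" + ("S" if leaflet is Leaflet.STROMAL else "L")
                    letter = None
                pathways.append(Pathway(steps=tuple(chain), leaflet=leaflet,
                                        terminal_core_letter=letter, code=code,
                                        complete=complete))
                return
            for _, nxt in sorted(g.out_edges(tip)):
                extend(chain + [g.edges[tip, nxt]["step"]])

        for src in sources:
            for _, nxt in sorted(g.out_edges(src)):
                extend([g.edges[src, nxt]["step"]])
    return pathways


def pathway_report(paths: Iterable[Pathway]) -> pd.DataFrame:
    """One row per step, grouped by pathway code, distances at 0.1 Angstrom."""
    rows = []
    for p in paths:
        for s in p.steps:
            rows.append({
                "code": p.code,
                "pathway": f"{s.donor_subunit}→{s.acceptor_subunit}",
                "donor_site": s.donor_site,
                "acceptor_site": s.acceptor_site,
                "distance_A": round_half_up(s.distance, 1),
                "location": s.leaflet.value.capitalize(),
                "efficient": s.efficient,
                "complete": p.complete,
            })
    columns = ["code", "pathway", "donor_site", "acceptor_site",
               "distance_A", "location", "efficient", "complete"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Flat edge-list fixtures (TSV)
# ---------------------------------------------------------------------------

EDGE_LIST_COLUMNS = ["donor_subunit", "donor_site", "acceptor_subunit",
                     "acceptor_site", "distance_A", "leaflet"]


def read_edge_list(path: str | Path) -> list[EETStep]:
    """Read a flat step edge list (TSV with the documented 6 columns)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_LIST_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"edge list {path} lacks columns: {missing}")
    steps = []
    for row in df.itertuples(index=False):
        steps.append(EETStep(
            donor_subunit=str(row.donor_subunit),
            acceptor_subunit=str(row.acceptor_subunit),
            donor_site=int(row.donor_site),
            acceptor_site=int(row.acceptor_site),
            distance=float(row.distance_A),
            leaflet=Leaflet(str(row.leaflet).lower()),
        ))
    return steps


def write_edge_list(steps: Iterable[EETStep], path: str | Path) -> None:
    rows = [{
        "donor_subunit": s.donor_subunit, "donor_site": s.donor_site,
        "acceptor_subunit": s.acceptor_subunit, "acceptor_site": s.acceptor_site,
        "distance_A": round_half_up(s.distance, 1), "leaflet": s.leaflet.value,
    } for s in steps]
    pd.DataFrame(rows, columns=EDGE_LIST_COLUMNS).to_csv(path, sep="\t", index=False)
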