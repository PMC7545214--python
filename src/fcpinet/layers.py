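"""Subunit contact graph and antenna layer (shell) classification.

Antenna subunits are organised in concentric layers around the core:
an innermost ring in direct protein contact with core subunits, a middle
ring attached to the innermost one, and so on.  Operationally a layer is
the breadth-first shell index in the chain contact graph, expanding from
all core subunits simultaneously: core = 0, innermost antennas = 1,
middle = 2, outermost = 3.

Two chains are in contact when any heavy-atom pair lies within
``contact_cutoff`` (default 4.0 Angstrom, the standard crystallographic
contact criterion); the edge weight is the minimal inter-chain distance.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import AnalysisError, ParameterError
from .structure_io import ChainAnnotation, Role, StructureModel

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 4.0


@dataclass
class ContactGraph:
    """Undirected chain-contact graph; nodes are subunit labels."""

    graph: nx.Graph
    contact_cutoff: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def min_distance(self, a: str, b: str) -> Optional[float]:
        if self.graph.has_edge(a, b):
            return self.graph.edges[a, b]["weight"]
        return None

    def to_json_dict(self) -> dict:
        return {
            "contact_cutoff": self.contact_cutoff,
            "nodes": sorted(self.graph.nodes),
            "edges": sorted(
                [sorted([u, v]) + [round(d["weight"], 3)]
                 for u, v, d in self.graph.edges(data=True)]
            ),
        }


@dataclass
class LayerAssignment:
    """Subunit label -> shell index (0 core, 1 innermost, ..., inf disconnected)."""

    shells: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def shell(self, subunit_label: str) -> float:
        return self.shells[subunit_label]

    def antennas_at(self, shell_index: int) -> list[str]:
        return sorted(k for k, v in self.shells.items() if v == shell_index and v >= 1)

    def to_frame(self, graph: Optional[ContactGraph] = None) -> pd.DataFrame:
        rows = []
        for label in sorted(self.shells):
            shell = self.shells[label]
            n_contacts = (graph.graph.degree(label)
                          if graph is not None and label in graph.graph else None)
            rows.append({"subunit": label,
                         "shell": shell if math.isfinite(shell) else "inf",
                         "n_contacts": n_contacts})
        return pd.DataFrame(rows, columns=["subunit", "shell", "n_contacts"])


def build_contact_graph(model: StructureModel,
                        contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                        ) -> ContactGraph:
    """Minimal heavy-atom distance graph over annotated chains.

    An edge is present iff some heavy-atom pair between the two chains is
    within ``contact_cutoff``; its weight is that minimal distance.
    """
    if contact_cutoff <= 0:
        raise ParameterError(f"contact_cutoff must be positive, got {contact_cutoff}")
    if len(model.chains) < 2:
        raise AnalysisError("contact graph needs at least 2 annotated chains")

    label_of = {c.chain_id: c.subunit_label for c in model.chains}
    coords: list[list[float]] = []
    chain_idx: list[int] = []
    chain_ids: list[str] = []
    index_of: dict[str, int] = {}
    for a in model.atoms:
        if a.element.upper() == "H":
            continue
        cid = a.chain_id
        if cid not in index_of:
            index_of[cid] = len(chain_ids)
            chain_ids.append(cid)
        coords.append(list(a.position))
        chain_idx.append(index_of[cid])

    g = nx.Graph()
    for c in model.chains:
        g.add_node(c.subunit_label)

    if coords:
        pts = np.asarray(coords)
        idx = np.asarray(chain_idx)
        tree = cKDTree(pts)
        pairs = tree.query_pairs(r=contact_cutoff, output_type="ndarray")
        if len(pairs):
            ci, cj = idx[pairs[:, 0]], idx[pairs[:, 1]]
            inter = ci != cj
            if inter.any():
                d = np.linalg.norm(pts[pairs[inter, 0]] - pts[pairs[inter, 1]], axis=1)
                for (i, j), dist in zip(
                        np.sort(np.stack([ci[inter], cj[inter]], axis=1), axis=1), d):
                    u = label_of.get(chain_ids[i], chain_ids[i])
                    v = label_of.get(chain_ids[j], chain_ids[j])
                    if not g.has_edge(u, v) or dist < g.edges[u, v]["weight"]:
                        g.add_edge(u, v, weight=float(dist))
    return ContactGraph(graph=g, contact_cutoff=contact_cutoff)


def assign_layers(graph: ContactGraph,
                  annotations: Iterable[ChainAnnotation]) -> LayerAssignment:
    """Breadth-first shell index from the set of core subunits.

    All core subunits are seeded at distance 0 simultaneously; an antenna's
    shell is its shortest contact-path length to any core subunit.
    Disconnected antennas get shell ``inf`` with a warning, and shells > 3
    (deeper than the three canonical layers) are reported as-is with a
    warning.
    """
    annotations = list(annotations)
    cores = [a.subunit_label for a in annotations if a.role is Role.CORE]
    if not cores:
        raise AnalysisError("layer assignment requires at least one core subunit")

    dist: dict[str, float] = {c: 0.0 for c in cores if c in graph.graph}
    queue = deque(dist)
    while queue:
        u = queue.popleft()
        for v in graph.graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)

    shells: dict[str, float] = {}
    warnings: list[str] = []
    for a in annotations:
        label = a.subunit_label
        if a.role is Role.CORE:
            shells[label] = 0.0
            continue
        shells[label] = dist.get(label, math.inf)
        if a.role is Role.ANTENNA:
            if math.isinf(shells[label]):
                warnings.append(f"antenna {label} is disconnected from the core")
            elif shells[label] > 3:
                warnings.append(f"antenna {label} sits at shell {int(shells[label])} "
                                f"(> 3 canonical layers)")
    for msg in warnings:
        logger.warning(msg)
    return LayerAssignment(shells=shells, warnings=warnings)
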