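"""Coordinate-file parsing and pigment extraction.

Reads an mmCIF (preferred) or legacy PDB file of a pigment-protein
supercomplex, annotates chains with subunit labels (core subunits such as
PsaA or peripheral antennas such as FCPI-8), and extracts one
:class:`PigmentRecord` per pigment cofactor.  Chlorophylls are represented
by their central Mg atom, carotenoids by the unweighted centroid of their
heavy atoms; all coordinates are in Angstrom.

Parsing is delegated to :mod:`gemmi`.  Alternate-location duplicates are
resolved deterministically by keeping the highest-occupancy conformer.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, ParseError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Enums and class groupings
# ---------------------------------------------------------------------------


class PigmentClass(str, enum.Enum):
    CHL_A = "chl_a"
    CHL_C = "chl_c"
    FUCOXANTHIN = "fucoxanthin"
    DIADINOXANTHIN = "diadinoxanthin"
    BETA_CAROTENE = "beta_carotene"
    OTHER_PIGMENT = "other_pigment"


CHLOROPHYLL_CLASSES = frozenset({PigmentClass.CHL_A, PigmentClass.CHL_C})
CAROTENOID_CLASSES = frozenset(
    {PigmentClass.FUCOXANTHIN, PigmentClass.DIADINOXANTHIN, PigmentClass.BETA_CAROTENE}
)

#: Author residue-number ranges that constitute antenna "site" numbering:
#: chlorophyll sites 400-423, carotenoid sites 301-307.
CHL_SITE_RANGE = (400, 423)
CAR_SITE_RANGE = (301, 307)


class Role(str, enum.Enum):
    CORE = "core"
    ANTENNA = "antenna"
    OTHER = "other"


class Leaflet(str, enum.Enum):
    STROMAL = "stromal"
    LUMENAL = "lumenal"


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the deposited model (post altloc resolution)."""

    chain_id: str
    residue_name: str
    residue_number: int
    atom_name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ParseError(f"non-finite coordinate for atom {self.atom_name} "
                             f"in {self.chain_id}/{self.residue_number}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ParseError(f"occupancy {self.occupancy} outside [0, 1] for atom "
                             f"{self.atom_name} in {self.chain_id}/{self.residue_number}")


_CORE_LABEL_RE = re.compile(r"^Psa([A-Z])$")
_ANTENNA_LABEL_RE = re.compile(r"^FCPI-(\d+)$")


@dataclass(frozen=True)
class ChainAnnotation:
    """Maps a chain ID to its subunit label and role.

    ``core_letter`` is the single uppercase letter used in pathway codes
    (PsaA -> "A", PsaR -> "R"); ``antenna_number`` is the antenna index
    (FCPI-8 -> 8).  Exactly one of the two is set unless role is ``other``.
    """

    chain_id: str
    subunit_label: str
    role: Role
    core_letter: Optional[str] = None
    antenna_number: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.role is Role.CORE) != (self.core_letter is not None):
            raise ConfigError(
                f"chain {self.chain_id} ({self.subunit_label}): core_letter must be "
                f"set iff role is core")
        if (self.role is Role.ANTENNA) != (self.antenna_number is not None):
            raise ConfigError(
                f"chain {self.chain_id} ({self.subunit_label}): antenna_number must "
                f"be set iff role is antenna")

    @classmethod
    def from_label(cls, chain_id: str, subunit_label: str) -> "ChainAnnotation":
        """Infer role/letter/number from a conventional subunit label."""
        m = _CORE_LABEL_RE.match(subunit_label)
        if m:
            return cls(chain_id, subunit_label, Role.CORE, core_letter=m.group(1))
        m = _ANTENNA_LABEL_RE.match(subunit_label)
        if m:
            return cls(chain_id, subunit_label, Role.ANTENNA,
                       antenna_number=int(m.group(1)))
        return cls(chain_id, subunit_label, Role.OTHER)


def load_chain_config(path: str | Path) -> list[ChainAnnotation]:
    """Read a chain -> subunit-label YAML mapping into annotations.

    The file is a flat mapping, e.g. ``h: PsaR`` or ``"1": FCPI-1``.
    Roles are inferred from label shape (Psa[A-Z] -> core, FCPI-n -> antenna).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"chain config not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"chain config {path} is not valid YAML: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"chain config {path} must be a mapping of chain -> label")
    annotations = [ChainAnnotation.from_label(str(cid), str(label))
                   for cid, label in raw.items()]
    numbers = [a.antenna_number for a in annotations if a.antenna_number is not None]
    if len(numbers) != len(set(numbers)):
        raise ConfigError(f"chain config {path}: duplicate antenna numbers")
    return annotations


@dataclass(frozen=True)
class PigmentClassMap:
    """Chemical-component code -> pigment class.

    In ``strict`` mode a chlorophyll residue without an Mg atom is a parse
    error; otherwise it is skipped with a warning.
    """

    mapping: Mapping[str, PigmentClass]
    strict: bool = False

    def __post_init__(self) -> None:
        # A plain dict cannot hold duplicate keys, but a config file could;
        # loaders must deduplicate-or-fail before reaching here.
        for code, cls in self.mapping.items():
            if not isinstance(cls, PigmentClass):
                raise ConfigError(f"component {code}: unknown pigment class {cls!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, strict: bool = False) -> "PigmentClassMap":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"pigment class map not found: {path}")
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"class map {path} is not valid YAML: {exc}") from exc
        if not isinstance(raw, Mapping):
            raise ConfigError(f"class map {path} must be a mapping of code -> class")
        mapping = {}
        for code, name in raw.items():
            try:
                mapping[str(code).upper()] = PigmentClass(str(name))
            except ValueError as exc:
                raise ConfigError(
                    f"class map {path}: unknown pigment class {name!r}") from exc
        return cls(mapping=mapping, strict=strict)

    @classmethod
    def default(cls, strict: bool = False) -> "PigmentClassMap":
        """The packaged default map (PDB Chemical Component Dictionary codes)."""
        from importlib.resources import files

        return cls.from_yaml(
            Path(str(files("fcpinet").joinpath("data/pigment_classes.yaml"))),
            strict=strict,
        )

    def get(self, residue_name: str) -> Optional[PigmentClass]:
        return self.mapping.get(residue_name.upper())


@dataclass
class PigmentRecord:
    """One pigment cofactor with its representative 3-D point (Angstrom).

    Chlorophyll records are built from the Mg atom; carotenoids from the
    heavy-atom centroid.  ``leaflet`` is filled in by the membrane stage;
    ``near_midplane`` flags chlorophylls within the midplane margin whose
    leaflet call is therefore uncertain.
    """

    chain_id: str
    residue_number: int
    pigment_class: PigmentClass
    subunit_label: str
    representative_point: np.ndarray
    leaflet: Optional[Leaflet] = None
    near_midplane: bool = False

    def __post_init__(self) -> None:
        self.representative_point = np.asarray(self.representative_point, dtype=float)
        if self.representative_point.shape != (3,):
            raise ParseError(f"representative point of {self.pigment_id} is not 3-D")
        if not np.all(np.isfinite(self.representative_point)):
            raise ParseError(f"non-finite representative point for {self.pigment_id}")

    @property
    def pigment_id(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)

    @property
    def is_chlorophyll(self) -> bool:
        return self.pigment_class in CHLOROPHYLL_CLASSES

    @property
    def is_carotenoid(self) -> bool:
        return self.pigment_class in CAROTENOID_CLASSES

    @property
    def site_number(self) -> Optional[int]:
        return extract_site_number(self)


def extract_site_number(record: PigmentRecord) -> Optional[int]:
    """Antenna site number of a pigment, if its residue number is one.

    Chlorophyll sites run 400-423 and carotenoid sites 301-307 in the
    antenna numbering convention; residue numbers outside the range for the
    pigment's class (e.g. core chlorophylls numbered in the 800s) yield
    ``None`` rather than an error.
    """
    n = record.residue_number
    if record.is_chlorophyll and CHL_SITE_RANGE[0] <= n <= CHL_SITE_RANGE[1]:
        return n
    if record.is_carotenoid and CAR_SITE_RANGE[0] <= n <= CAR_SITE_RANGE[1]:
        return n
    return None


@dataclass
class StructureModel:
    """Parsed supercomplex: atoms, chain annotations, pigment records."""

    atoms: list[AtomRecord]
    chains: list[ChainAnnotation]
    pigments: list[PigmentRecord]
    source_id: str = ""

    def __post_init__(self) -> None:
        known = {c.chain_id for c in self.chains}
        for p in self.pigments:
            if p.chain_id not in known:
                raise ParseError(f"pigment {p.pigment_id} references unknown chain "
                                 f"{p.chain_id!r}")

    def annotation(self, chain_id: str) -> ChainAnnotation:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def annotations_by_label(self) -> dict[str, ChainAnnotation]:
        return {c.subunit_label: c for c in self.chains}

    def chlorophylls(self) -> list[PigmentRecord]:
        return [p for p in self.pigments if p.is_chlorophyll]

    def pigments_of_class(self, pigment_class: PigmentClass) -> list[PigmentRecord]:
        return [p for p in self.pigments if p.pigment_class is pigment_class]

    def class_counts(self) -> dict[PigmentClass, int]:
        counts: dict[PigmentClass, int] = {}
        for p in self.pigments:
            counts[p.pigment_class] = counts.get(p.pigment_class, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_MG_NAMES = {"MG", "Mg"}


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: the highest occupancy, first on tie."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order for determinism
    seen: set[str] = set()
    out = []
    for atom in residue:
        if atom.name not in seen and best[atom.name] is atom:
            seen.add(atom.name)
            out.append(atom)
        elif atom.name not in seen and best[atom.name] is not atom:
            seen.add(atom.name)
            out.append(best[atom.name])
    return out


def _build_pigment(chain_id: str, residue: gemmi.Residue,
                   pigment_class: PigmentClass, subunit_label: str,
                   atoms: Sequence[gemmi.Atom], strict: bool) -> Optional[PigmentRecord]:
    if pigment_class in CHLOROPHYLL_CLASSES:
        mg = next((a for a in atoms
                   if a.element.name.upper() == "MG" or a.name.upper() in _MG_NAMES),
                  None)
        if mg is None:
            msg = (f"chlorophyll residue {residue.name} {chain_id}/"
                   f"{residue.seqid.num} has no Mg atom")
            if strict:
                raise ParseError(msg)
            logger.warning("%s; skipping record", msg)
            return None
        point = np.array([mg.pos.x, mg.pos.y, mg.pos.z])
    else:
        heavy = [a for a in atoms if a.element.name.upper() != "H"]
        if not heavy:
            logger.warning("pigment residue %s %s/%s has no heavy atoms; skipping",
                           residue.name, chain_id, residue.seqid.num)
            return None
        point = np.mean([[a.pos.x, a.pos.y, a.pos.z] for a in heavy], axis=0)
    return PigmentRecord(
        chain_id=chain_id,
        residue_number=residue.seqid.num,
        pigment_class=pigment_class,
        subunit_label=subunit_label,
        representative_point=point,
    )


def parse_structure(path: str | Path,
                    class_map: Optional[PigmentClassMap] = None,
                    chain_config: Optional[Iterable[ChainAnnotation]] = None,
                    ) -> StructureModel:
    """Parse an mmCIF/PDB file into a :class:`StructureModel`.

    Every atom of the first model is read (altloc duplicates resolved by
    occupancy); one :class:`PigmentRecord` is produced per residue whose
    chemical-component code appears in ``class_map``.  Chains without an
    annotation in ``chain_config`` are annotated with role ``other`` under
    their own chain ID.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"coordinate file not found: {path}")
    if class_map is None:
        class_map = PigmentClassMap.default()
    try:
        structure = gemmi.read_structure(str(path), merge_chain_parts=True)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise ParseError(f"{path} contains no models")
    model = structure[0]

    annotations: dict[str, ChainAnnotation] = {}
    for ann in (chain_config or []):
        annotations[ann.chain_id] = ann

    atoms: list[AtomRecord] = []
    pigments: list[PigmentRecord] = []
    chains: list[ChainAnnotation] = []
    for chain in model:
        ann = annotations.get(chain.name)
        if ann is None:
            ann = ChainAnnotation(chain.name, chain.name, Role.OTHER)
        chains.append(ann)
        for residue in chain:
            resolved = _resolve_altlocs(residue)
            for atom in resolved:
                atoms.append(AtomRecord(
                    chain_id=chain.name,
                    residue_name=residue.name,
                    residue_number=residue.seqid.num,
                    atom_name=atom.name,
                    element=atom.element.name,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    altloc=atom.altloc or "",
                ))
            pigment_class = class_map.get(residue.name)
            if pigment_class is not None:
                rec = _build_pigment(chain.name, residue, pigment_class,
                                     ann.subunit_label, resolved, class_map.strict)
                if rec is not None:
                    pigments.append(rec)
    # annotated chains absent from the file are still carried (empty chains)
    for cid, ann in annotations.items():
        if all(c.chain_id != cid for c in chains):
            chains.append(ann)
    return StructureModel(atoms=atoms, chains=chains, pigments=pigments,
                          source_id=path.stem)


def pigment_table(model: StructureModel) -> pd.DataFrame:
    """One row per pigment: chain, subunit, class, site, x, y, z, leaflet.

    ``near_midplane`` marks chlorophylls whose membrane projection falls
    within the midplane margin (leaflet call uncertain).
    """
    rows = []
    for p in model.pigments:
        x, y, z = p.representative_point
        rows.append({
            "chain": p.chain_id,
            "subunit": p.subunit_label,
            "class": p.pigment_class.value,
            "site": p.site_number,
            "x": x, "y": y, "z": z,
            "leaflet": p.leaflet.value if p.leaflet else None,
            "near_midplane": p.near_midplane,
        })
    columns = ["chain", "subunit", "class", "site", "x", "y", "z",
               "leaflet", "near_midplane"]
    return pd.DataFrame(rows, columns=columns)
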