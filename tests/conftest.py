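"""Shared fixtures: hand-written mmCIF snippets and generated toy models."""

from __future__ import annotations

import numpy as np
import pytest

from fcpinet import (
    ChainAnnotation,
    Leaflet,
    PigmentClass,
    PigmentRecord,
    StructureModel,
    parse_structure,
)
from fcpinet.synth import SyntheticSpec, generate

MMCIF_HEADER = """data_synthetic
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
"""


def atom_line(serial, name, element, comp, chain, seq, x, y, z,
              occ=1.0, alt="."):
    return (f"HETATM {serial} {element} {name} {alt} {comp} {chain} 1 . ? "
            f"{x:.3f} {y:.3f} {z:.3f} {occ:.2f} 20.00 {seq} {chain} 1\n")


def write_cif(tmp_path, lines, name="model.cif"):
    path = tmp_path / name
    path.write_text(MMCIF_HEADER + "".join(lines))
    return path


@pytest.fixture
def one_chl_cif(tmp_path):
    """A single chain bearing a single chlorophyll a (Mg at the origin)."""
    return write_cif(tmp_path,
                     [atom_line(1, "MG", "MG", "CLA", "A", 401, 0.0, 0.0, 0.0)])


def make_record(chain, resnum, cls, point, subunit=None, leaflet=None):
    return PigmentRecord(
        chain_id=chain, residue_number=resnum, pigment_class=cls,
        subunit_label=subunit or chain,
        representative_point=np.asarray(point, dtype=float), leaflet=leaflet)


def make_model(pigments, labels=None):
    """StructureModel with annotations inferred from subunit labels."""
    chains = {}
    for p in pigments:
        label = (labels or {}).get(p.chain_id, p.subunit_label)
        chains.setdefault(p.chain_id, ChainAnnotation.from_label(p.chain_id, label))
    return StructureModel(atoms=[], chains=list(chains.values()),
                          pigments=list(pigments), source_id="test")


@pytest.fixture
def two_plane_model():
    """20 Chl a on planes z=0 and z=20: ground-truth leaflet split."""
    pigments = []
    rng = np.random.default_rng(42)
    xy = rng.uniform(-30, 30, size=(10, 2))
    # identical in-plane clouds: the cross-covariance with z vanishes exactly,
    # so the thin covariance axis is exactly (0, 0, 1)
    for i, (x, y) in enumerate(xy):
        pigments.append(make_record("A", 400 + i, PigmentClass.CHL_A, (x, y, 0.0)))
    for i, (x, y) in enumerate(xy):
        pigments.append(make_record("A", 410 + i, PigmentClass.CHL_A, (x, y, 20.0)))
    truth = {(p.chain_id, p.residue_number):
             (Leaflet.STROMAL if p.representative_point[2] > 10 else Leaflet.LUMENAL)
             for p in pigments}
    return make_model(pigments), truth


SMALL_SPEC = SyntheticSpec(n_core_subunits=3, n_rings=2, antennas_per_ring=(4, 4),
                           chl_a_per_subunit=6, chl_c_per_subunit=1,
                           car_per_subunit=2, seed=11)


@pytest.fixture(scope="session")
def small_synthetic(tmp_path_factory):
    """Generated 3-core / 4+4-antenna toy complex, with ground truth."""
    path = tmp_path_factory.mktemp("synth") / "small.cif"
    text, truth = generate(SMALL_SPEC, out_path=path)
    return path, truth


@pytest.fixture(scope="session")
def default_synthetic(tmp_path_factory):
    """The default paper-scale toy complex (12 cores, 11/10/3 antenna rings)."""
    path = tmp_path_factory.mktemp("synth") / "default.cif"
    text, truth = generate(SyntheticSpec(seed=5), out_path=path)
    return path, truth


def annotations_from_truth(truth):
    return [ChainAnnotation.from_label(cid, label)
            for cid, label in truth.chain_labels.items()]


def parse_truth_model(path, truth):
    return parse_structure(path, chain_config=annotations_from_truth(truth))
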