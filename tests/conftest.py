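"""Shared fixtures: tiny handwritten structure files and model builders."""

from __future__ import annotations

import numpy as np
import pytest

from rnapcollide.structio import AtomRecord, StructureModel

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.560   6.351  -6.430  1.00  0.00           C
ATOM      3  C   ALA A   1      13.276   5.262  -5.641  1.00  0.00           C
END
"""

# the same three atoms as MINIMAL_PDB, expressed as mmCIF
MINIMAL_CIF = """\
data_minimal
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
ATOM 1 N N   . ALA A 1 1 ? 11.104 6.134 -6.504 1.00 0.00 1 A
ATOM 2 C CA  . ALA A 1 1 ? 12.560 6.351 -6.430 1.00 0.00 1 A
ATOM 3 C C   . ALA A 1 1 ? 13.276 5.262 -5.641 1.00 0.00 1 A
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1      10.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1      20.000   0.000   0.000  0.40  0.00           C
END
"""


def make_atom(
    chain: str = "X",
    num: int = 1,
    name: str = "C1",
    element: str = "C",
    pos=(0.0, 0.0, 0.0),
    mass: float | None = None,
) -> AtomRecord:
    default_mass = {"C": 12.011, "O": 15.999, "N": 14.007, "P": 30.974, "H": 1.008}
    return AtomRecord(
        chain_id=chain,
        residue_number=num,
        residue_name="LIG",
        atom_name=name,
        element=element,
        occupancy=1.0,
        altloc="",
        position=np.asarray(pos, dtype=float),
        mass=mass if mass is not None else default_mass.get(element, 12.011),
    )


def make_ca_chain(
    chain: str, n_residues: int, rng: np.random.Generator, spacing: float = 3.8
) -> list[AtomRecord]:
    """Non-degenerate CA trace: random-walk curve with fixed step length."""
    directions = rng.normal(size=(n_residues, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    pts = np.cumsum(directions * spacing, axis=0) + rng.uniform(-20, 20, 3)
    return [
        make_atom(chain, i + 1, "CA", "C", pts[i]) for i in range(n_residues)
    ]


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def minimal_cif(tmp_path):
    path = tmp_path / "minimal.cif"
    path.write_text(MINIMAL_CIF)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
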