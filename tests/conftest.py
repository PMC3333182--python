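"""Shared fixtures: canonical catalogue, toy alignments and toy structures."""
from __future__ import annotations

import textwrap

import numpy as np
import pytest

from mannomap.catalogue import canonical_fixture
from mannomap.structure import Atom, Residue, StructureModel
from mannomap.synthetic import SyntheticSpec


@pytest.fixture(scope="session")
def records():
    return canonical_fixture()

@pytest.fixture(scope="session")
def records_by_id(records):
    return {r.id: r for r in records}


@pytest.fixture
def synthetic_spec():
    return SyntheticSpec(
        seed=11,
        n_residues=120,
        planted_clusters=((30, 90, 3), (200, 260, 3)),
        probe_distances=((110, 2.0), (115, 25.0)),
    )


def make_structure(atoms_by_residue: dict[int, list[tuple[str, str, tuple[float, float, float]]]],
                   names: dict[int, str] | None = None) -> StructureModel:
    """Build a StructureModel from {residue number: [(atom, element, xyz)]}."""
    names = names or {}
    residues = tuple(
        Residue(
            number=num,
            name=names.get(num, "GLY"),
            atoms=tuple(Atom(a, e, xyz) for a, e, xyz in atom_list),
        )
        for num, atom_list in sorted(atoms_by_residue.items())
    )
    return StructureModel(chain_id="A", residues=residues)


def random_structure(rng: np.random.Generator, n_residues: int = 6,
                     max_atoms: int = 4) -> StructureModel:
    """A random toy structure with 1..max_atoms atoms per residue."""
    atoms_by_residue = {}
    for num in range(1, n_residues + 1):
        k = int(rng.integers(1, max_atoms + 1))
        atoms_by_residue[num] = [
            (f"A{j}", "C", tuple(map(float, rng.uniform(-20, 20, 3)))) for j in range(k)
        ]
    return make_structure(atoms_by_residue)


TOY_PDB = textwrap.dedent("""\
    ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
    ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
    ATOM      3  CA  GLY A   2       3.000   4.000   0.000  1.00  0.00           C
    HETATM    4  C1  NAG A 901      10.000  10.000  10.000  1.00  0.00           C
    ATOM      5  O   HOH A 902      20.000  20.000  20.000  1.00  0.00           O
    END
    """)


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path
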