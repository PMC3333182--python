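"""3-D structure reading and active-site proximity analysis.

Beta-mannosidase houses its two catalytic nucleophiles (E457, E554) in a TIM
barrel; W190, D191, W192 on an extended loop plus W390 and W657 grip the
substrate.  This module reads PDB coordinates (via Biopython), computes
minimal heavy-atom residue-residue distances, the distance of any residue to
the active site, an inclusive close/away proximity call, and simple
distance-only contact detection (salt bridge, hydrogen-bond candidate) used
in substitution rationales.

Hydrogens are dropped at parse time — homology models and X-ray templates
lack them — and waters are ignored throughout.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "StructureError",
    "Atom",
    "Residue",
    "StructureModel",
    "ActiveSiteDefinition",
    "ContactReport",
    "human_active_site",
    "read_structure",
    "min_residue_distance",
    "distance_to_active_site",
    "proximity_class",
    "detect_contacts",
]

_WATER_NAMES = {"HOH", "WAT", "DOD"}

# Side-chain atoms carrying formal charge at physiological pH.
_BASIC_N = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


class StructureError(ValueError):
    """Raised for unreadable coordinate files or missing residues."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    number: int
    name: str  # 3-letter code
    atoms: tuple[Atom, ...]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class StructureModel:
    """Heavy-atom coordinates of one chain plus any non-water ligands."""

    chain_id: str
    residues: tuple[Residue, ...]
    ligands: tuple[Residue, ...] = ()

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise StructureError("residue numbers must be strictly increasing")
        for r in self.residues:
            if not np.isfinite(r.coords).all():
                raise StructureError(f"non-finite coordinates in residue {r.number}")

    def residue(self, number: int) -> Residue:
        for r in self.residues:
            if r.number == number:
                return r
        raise StructureError(f"residue {number} not present in chain {self.chain_id}")

    def has_residue(self, number: int) -> bool:
        return any(r.number == number for r in self.residues)

    # -- PDB writing (fixed-width ATOM records) ------------------------------
    def to_pdb_string(self) -> str:
        lines = []
        serial = 1
        for rec, residues in (("ATOM", self.residues), ("HETATM", self.ligands)):
            for res in residues:
                for atom in res.atoms:
                    x, y, z = atom.coord
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                    lines.append(
                        f"{rec:<6s}{serial:>5d} {name}{'':1s}{res.name:>3s} "
                        f"{self.chain_id:1s}{res.number:>4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}"
                    )
                    serial += 1
        lines.append("END")
        return "\n".join(lines) + "\n"

    def to_pdb(self, path: str | Path) -> None:
        Path(path).write_text(self.to_pdb_string())


@dataclass(frozen=True)
class ActiveSiteDefinition:
    """Catalytic nucleophiles plus substrate-binding residues of one species.

    Default human definition: catalytic E457/E554; binding W190, D191, W192,
    W390, W657.  ``numbering`` records whether positions are precursor or
    mature coordinates.
    """

    catalytic: frozenset[int] = frozenset({457, 554})
    binding: frozenset[int] = frozenset({190, 191, 192, 390, 657})
    numbering: str = "precursor"

    def __post_init__(self) -> None:
        if self.catalytic & self.binding:
            raise ValueError("catalytic and binding sets must be disjoint")
        if any(p < 1 for p in self.all_positions):
            raise ValueError("active-site positions must be >= 1")

    @property
    def all_positions(self) -> frozenset[int]:
        return self.catalytic | self.binding


def human_active_site() -> ActiveSiteDefinition:
    """The seven-residue human beta-mannosidase active site (precursor numbering)."""
    return ActiveSiteDefinition()


def read_structure(path: str | Path, chain_id: str | None = None) -> StructureModel:
    """Read one chain from a PDB file into a :class:`StructureModel`.

    ATOM records become residues; non-water HETATM records are kept in a
    separate ligand list; waters and hydrogens are dropped.
    """
    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_struct = parser.get_structure("model", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(bio_struct)
    if not models:
        raise StructureError(f"no coordinates found in {path}")
    chains = list(models[0])
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
    if not chains:
        raise StructureError(f"no matching chain found in {path}")
    chain = chains[0]

    residues: list[Residue] = []
    ligands: list[Residue] = []
    for res in chain:
        hetflag, resseq, _ = res.id
        name = res.get_resname().strip()
        if name in _WATER_NAMES or hetflag == "W":
            continue
        atoms = tuple(
            Atom(a.get_name(), (a.element or "").strip().upper(), tuple(map(float, a.coord)))
            for a in res
            if (a.element or "").strip().upper() != "H"
        )
        if not atoms:
            continue
        target = ligands if hetflag.strip() else residues
        target.append(Residue(number=int(resseq), name=name, atoms=atoms))
    if not residues and not ligands:
        raise StructureError(f"no atoms parsed from {path}")
    return StructureModel(chain_id=chain.id, residues=tuple(residues), ligands=tuple(ligands))


def min_residue_distance(s: StructureModel, i: int, j: int) -> float:
    """Minimum heavy-atom distance (A) between residues ``i`` and ``j``."""
    if i == j:
        s.residue(i)  # existence check
        return 0.0
    a, b = s.residue(i), s.residue(j)
    return float(cdist(a.coords, b.coords).min())


def distance_to_active_site(
    s: StructureModel, residue: int, as_def: ActiveSiteDefinition
) -> tuple[float, int]:
    """Minimal distance from a residue to any active-site residue.

    Returns ``(distance_A, nearest active-site residue)``; ties are broken by
    the lower residue number (positions are scanned in ascending order and
    only a strictly smaller distance replaces the incumbent).
    """
    present = [p for p in sorted(as_def.all_positions) if s.has_residue(p)]
    if not present:
        raise StructureError("no active-site residue present in the model")
    best_d, best_p = float("inf"), -1
    for p in present:
        d = min_residue_distance(s, residue, p)
        if d < best_d:
            best_d, best_p = d, p
    return best_d, best_p


def proximity_class(distance: float, threshold: float = 8.0) -> str:
    """'close' iff distance <= threshold (boundary inclusive), else 'away'."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return "close" if distance <= threshold else "away"


@dataclass(frozen=True)
class ContactReport:
    """Geometric interaction classes between one residue pair."""

    residue_i: int
    residue_j: int
    min_distance_A: float
    classes: frozenset[str]  # subset of {"salt_bridge", "hbond_candidate"}


def detect_contacts(
    s: StructureModel,
    i: int,
    j: int,
    salt_bridge_A: float = 4.0,
    hbond_A: float = 3.5,
) -> ContactReport:
    """Distance-only contact detection between residues ``i`` and ``j``.

    Salt bridge: a basic side-chain nitrogen (Arg NE/NH1/NH2, Lys NZ, His
    ND1/NE2) within ``salt_bridge_A`` of an acidic side-chain oxygen (Asp
    OD1/OD2, Glu OE1/OE2).  Hydrogen-bond candidate: any N/O heavy-atom pair
    within ``hbond_A``.  No angular terms.
    """
    a, b = s.residue(i), s.residue(j)
    dist = min_residue_distance(s, i, j)
    classes: set[str] = set()

    def _pairs_within(atoms_a: Iterable[Atom], atoms_b: Iterable[Atom], cutoff: float) -> bool:
        pa = np.array([x.coord for x in atoms_a], dtype=float)
        pb = np.array([x.coord for x in atoms_b], dtype=float)
        if pa.size == 0 or pb.size == 0:
            return False
        return bool(cdist(pa, pb).min() <= cutoff)

    for first, second in ((a, b), (b, a)):
        basic = [x for x in first.atoms if x.name in _BASIC_N.get(first.name, ())]
        acidic = [x for x in second.atoms if x.name in _ACIDIC_O.get(second.name, ())]
        if basic and acidic and _pairs_within(basic, acidic, salt_bridge_A):
            classes.add("salt_bridge")

    polar_a = [x for x in a.atoms if x.element in ("N", "O")]
    polar_b = [x for x in b.atoms if x.element in ("N", "O")]
    if _pairs_within(polar_a, polar_b, hbond_A):
        classes.add("hbond_candidate")

    if not classes and not (polar_a and polar_b):
        warnings.warn(f"residues {i}/{j} lack polar side-chain atoms; contact class 'none'")
    return ContactReport(i, j, dist, frozenset(classes))
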