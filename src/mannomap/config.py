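"""Shared configuration: thresholds, the per-species table and conservation groups.

All tunable knobs of the pipeline live here so that a single YAML file can
reproduce a run.  Distances are in Angstrom, residue positions in precursor
(signal-peptide-included) numbering unless stated otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "Thresholds",
    "SpeciesInfo",
    "SPECIES_TABLE",
    "CLUSTAL_STRONG_GROUPS",
    "CLUSTAL_WEAK_GROUPS",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class Thresholds:
    """Distance and rule thresholds used by structure and severity analysis.

    Attributes
    ----------
    proximity_A:
        A residue whose minimal heavy-atom distance to the active site is at
        most this is called "close to the active site" (boundary inclusive).
    direct_interaction_A:
        Below this the residue is treated as directly interacting with the
        active site (severe class for substitutions).
    salt_bridge_A:
        Basic-N / acidic-O heavy-atom cutoff for a salt bridge.
    hbond_A:
        Donor-acceptor heavy-atom cutoff for a hydrogen-bond candidate
        (distance-only criterion, no angles).
    last_domain_boundary:
        Human precursor residue number at which the C-terminal domain region
        starts; truncations stopping before it destabilize the fold and are
        classed severe.
    gap_threshold_nt:
        Maximum nucleotide gap between consecutive mutations inside one
        hot-spot segment (strictly larger gaps split segments).
    catalytic_adjacency:
        Sequence distance within which a residue counts as adjacent to a
        catalytic nucleophile (e.g. N455 vs E457).
    """

    proximity_A: float = 8.0
    direct_interaction_A: float = 4.5
    salt_bridge_A: float = 4.0
    hbond_A: float = 3.5
    last_domain_boundary: int = 720
    gap_threshold_nt: int = 150
    catalytic_adjacency: int = 2

    def __post_init__(self) -> None:
        for name in ("proximity_A", "direct_interaction_A", "salt_bridge_A", "hbond_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.last_domain_boundary < 1 or self.gap_threshold_nt < 1:
            raise ValueError("last_domain_boundary and gap_threshold_nt must be >= 1")


@dataclass(frozen=True)
class SpeciesInfo:
    """Per-species constants.

    signal_peptide_len : N-terminal signal peptide removed in the mature
        protein (17 aa; 19 in mouse).
    chitobiase_rescue : whether the exoglycosidase chitobiase is highly
        expressed and can partially compensate for beta-mannosidase loss
        (human and rodents yes; ruminants no).
    precursor_length : UniProt-annotated precursor protein length in residues.
    """

    signal_peptide_len: int
    chitobiase_rescue: bool
    precursor_length: int


#: Default species table for lysosomal beta-mannosidase (MANBA product).
SPECIES_TABLE: Mapping[str, SpeciesInfo] = {
    "human": SpeciesInfo(signal_peptide_len=17, chitobiase_rescue=True, precursor_length=879),
    "cow": SpeciesInfo(signal_peptide_len=17, chitobiase_rescue=False, precursor_length=879),
    "goat": SpeciesInfo(signal_peptide_len=17, chitobiase_rescue=False, precursor_length=879),
    "mouse": SpeciesInfo(signal_peptide_len=19, chitobiase_rescue=True, precursor_length=880),
}

# Amino-acid conservation groups of the Clustal family of alignment tools.
# A fully mutated column within one strong group is "conservative" (:), within
# one weak group "semi_conservative" (.), otherwise non-conserved.
CLUSTAL_STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)
CLUSTAL_WEAK_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g)
    for g in (
        "CSA", "ATV", "SAG", "STNK", "STPA", "SGND",
        "SDEQN", "NDEQHK", "NEQHRK", "FVLIM", "HFY",
    )
)


def dump_config(thresholds: Thresholds, species: Mapping[str, SpeciesInfo], path: str | Path) -> None:
    """Write thresholds and the species table to a YAML file."""
    payload = {
        "thresholds": asdict(thresholds),
        "species": {name: asdict(info) for name, info in species.items()},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_config(path: str | Path) -> tuple[Thresholds, dict[str, SpeciesInfo]]:
    """Read a YAML file written by :func:`dump_config` (round-trips unchanged)."""
    payload = yaml.safe_load(Path(path).read_text())
    thresholds = Thresholds(**payload.get("thresholds", {}))
    species = {
        name: SpeciesInfo(**info) for name, info in payload.get("species", {}).items()
    }
    return thresholds, species
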