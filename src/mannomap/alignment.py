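"""Profile-alignment position mapping and cross-species mutation extrapolation.

Mature (signal-peptide-trimmed) beta-mannosidase sequences from human, cow,
goat and mouse are near-identical in the regions carrying disease mutations,
which makes a profile alignment a reliable bridge: a residue observed mutated
in one species can be transferred to the homologous position in another and
scored for conservation.  Catalogue positions are precursor-numbered;
alignment rows hold mature sequences, so mapping converts through the
species' signal-peptide lengths.

Column conservation follows the Clustal convention: identical (*) columns,
columns within one strong group (:) are conservative, within one weak group
(.) semi-conservative, otherwise non-conserved.  Columns containing a gap are
non-conserved.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import AlignIO

from .catalogue import MutationRecord
from .config import CLUSTAL_STRONG_GROUPS, CLUSTAL_WEAK_GROUPS, SPECIES_TABLE, SpeciesInfo

__all__ = [
    "AlignmentError",
    "ProfileAlignment",
    "PositionMap",
    "ExtrapolatedMutation",
    "read_alignment",
    "trim_signal_peptide",
    "map_position",
    "column_conservation",
    "build_position_map",
    "extrapolate_mutations",
    "write_extrapolation_tsv",
]

GAP = "-"
_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO") | {GAP}


class AlignmentError(ValueError):
    """Raised for unreadable or inconsistent alignments."""


@dataclass(frozen=True)
class ProfileAlignment:
    """An ordered multiple alignment: (label, gapped sequence) rows."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment rows (lengths {sorted(lengths)})")
        for label, seq in self.rows:
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise AlignmentError(f"row {label!r} has unknown characters {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.rows)

    def row(self, label: str) -> str:
        for lab, seq in self.rows:
            if lab == label:
                return seq
        raise AlignmentError(f"unknown species label {label!r}")

    def column(self, index: int) -> tuple[str, ...]:
        """Residues of column ``index`` (0-based)."""
        if not 0 <= index < self.n_columns:
            raise AlignmentError(f"column {index} out of range 0..{self.n_columns - 1}")
        return tuple(seq[index] for _, seq in self.rows)

    def ungapped(self, label: str) -> str:
        return self.row(label).replace(GAP, "")


def read_alignment(path: str | Path) -> ProfileAlignment:
    """Read a Clustal (.aln) or aligned-FASTA alignment.

    The two encodings of the same alignment parse to equal objects.  Format is
    sniffed from the content; ragged rows or unknown characters raise
    :class:`AlignmentError` naming the problem.
    """
    text = Path(path).read_text()
    fmt = "clustal" if text.lstrip().upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(StringIO(text), fmt)
    except ValueError as exc:
        raise AlignmentError(f"cannot parse alignment {path}: {exc}") from exc
    return ProfileAlignment(tuple((rec.id, str(rec.seq).upper()) for rec in aln))


def trim_signal_peptide(
    seq: str, species: str, species_table: Mapping[str, SpeciesInfo] = SPECIES_TABLE
) -> str:
    """Remove the N-terminal signal peptide (17 aa; 19 in mouse).

    Maps precursor numbering to mature numbering: mature position =
    precursor position - signal length.
    """
    info = species_table.get(species)
    if info is None:
        raise AlignmentError(f"unknown species {species!r}")
    n = info.signal_peptide_len
    if len(seq) <= n:
        raise AlignmentError(
            f"sequence of length {len(seq)} shorter than the {n}-residue signal peptide"
        )
    return seq[n:]


def _pos_to_column(row: str) -> list[int]:
    """0-based alignment column of each 1-based ungapped position."""
    return [i for i, c in enumerate(row) if c != GAP]


def map_position(
    aln: ProfileAlignment, from_species: str, pos: int, to_species: str
) -> int | None:
    """Transfer an ungapped (mature) residue position between alignment rows.

    Finds the column holding position ``pos`` of the source row and returns
    the target row's ungapped index at that column, or None when the target
    is gapped there.  Strictly increasing and round-trip consistent where
    defined.
    """
    src = aln.row(from_species)
    cols = _pos_to_column(src)
    if not 1 <= pos <= len(cols):
        raise AlignmentError(
            f"position {pos} outside the ungapped length {len(cols)} of {from_species!r}"
        )
    col = cols[pos - 1]
    tgt = aln.row(to_species)
    if tgt[col] == GAP:
        return None
    return len(tgt[:col + 1].replace(GAP, ""))


@dataclass(frozen=True)
class PositionMap:
    """A partial, strictly increasing residue-position map between two rows."""

    source: str
    target: str
    mapping: dict[int, int]


def build_position_map(aln: ProfileAlignment, source: str, target: str) -> PositionMap:
    src = aln.row(source)
    mapping: dict[int, int] = {}
    for pos in range(1, len(src.replace(GAP, "")) + 1):
        mapped = map_position(aln, source, pos, target)
        if mapped is not None:
            mapping[pos] = mapped
    return PositionMap(source, target, mapping)


def column_conservation(aln: ProfileAlignment, column: int) -> str:
    """Clustal-style conservation class of one alignment column.

    'identical' iff all residues equal; else 'conservative' when all residues
    fall in one strong group, 'semi_conservative' when in one weak group,
    else 'non_conserved'.  Any gap makes a column non-conserved.
    """
    residues = aln.column(column)
    if GAP in residues:
        return "non_conserved"
    unique = set(residues)
    if len(unique) == 1:
        return "identical"
    if any(unique <= group for group in CLUSTAL_STRONG_GROUPS):
        return "conservative"
    if any(unique <= group for group in CLUSTAL_WEAK_GROUPS):
        return "semi_conservative"
    return "non_conserved"


@dataclass(frozen=True)
class ExtrapolatedMutation:
    """One observed mutation transferred to a homologous position elsewhere.

    ``target_pos`` is precursor-numbered in the target species, None when the
    alignment column is gapped there.  ``predicted_severity`` is filled by the
    severity module when requested.
    """

    origin_id: str
    origin_species: str
    origin_pos: int
    target_species: str
    target_pos: int | None
    target_wt_residue: str | None
    conserved: str
    predicted_severity: str | None = None


def extrapolate_mutations(
    records: Sequence[MutationRecord],
    aln: ProfileAlignment,
    target_species: str,
    species_table: Mapping[str, SpeciesInfo] = SPECIES_TABLE,
) -> list[ExtrapolatedMutation]:
    """Map each record's mutated residue to the homologous target position.

    Converts precursor catalogue positions to mature alignment positions via
    the source signal length, transfers across the alignment, then back to
    precursor numbering with the target signal length.  Records whose column
    is gapped in the target are emitted with ``target_pos`` None.
    Extrapolating a record to its own species returns its own position.
    """
    out: list[ExtrapolatedMutation] = []
    tgt_signal = species_table[target_species].signal_peptide_len
    for rec in records:
        sp = rec.species.value
        src_signal = species_table[sp].signal_peptide_len
        mature_pos = rec.protein_pos - src_signal
        if mature_pos < 1:
            raise AlignmentError(f"{rec.id}: position lies inside the signal peptide")
        src_row = aln.row(sp)
        cols = _pos_to_column(src_row)
        col = cols[mature_pos - 1]
        mapped = map_position(aln, sp, mature_pos, target_species)
        if mapped is None:
            out.append(ExtrapolatedMutation(
                origin_id=rec.id, origin_species=sp, origin_pos=rec.protein_pos,
                target_species=target_species, target_pos=None,
                target_wt_residue=None,
                conserved=column_conservation(aln, col),
            ))
            continue
        tgt_row = aln.ungapped(target_species)
        out.append(ExtrapolatedMutation(
            origin_id=rec.id, origin_species=sp, origin_pos=rec.protein_pos,
            target_species=target_species, target_pos=mapped + tgt_signal,
            target_wt_residue=tgt_row[mapped - 1],
            conserved=column_conservation(aln, col),
        ))
    return out


def write_extrapolation_tsv(
    rows: Sequence[ExtrapolatedMutation], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "origin_id": r.origin_id,
                "origin_species": r.origin_species,
                "origin_pos": r.origin_pos,
                "target_species": r.target_species,
                "target_pos": r.target_pos if r.target_pos is not None else ".",
                "target_wt_residue": r.target_wt_residue or ".",
                "conserved": r.conserved,
                "predicted_severity": r.predicted_severity or ".",
            }
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)
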