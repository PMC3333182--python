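"""The inherited-mutation catalogue for beta-mannosidosis.

Beta-mannosidosis is a rare autosomal-recessive lysosomal storage disorder
caused by mutations in *MANBA*, the gene encoding lysosomal beta-D-mannosidase.
This module holds the data model for one catalogued mutation
(:class:`MutationRecord`), a parser for the compact protein-change notation
used in the clinical literature (``W466X``, ``R182W``), the consequence
classifier (truncating vs substitution), TSV round-trip I/O and summary
statistics.

The bundled :func:`canonical_fixture` transcribes the fifteen disease-causing
mutations reported across human, goat and cow: thirteen human alleles (nine
truncating, four missense), one goat allele (W466X, also observed in a human
compound heterozygote) and one cow allele (W858X).
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Species",
    "EventKind",
    "Zygosity",
    "Phenotype",
    "Consequence",
    "MutationRecord",
    "CatalogueSummary",
    "CatalogueError",
    "parse_protein_notation",
    "classify_consequence",
    "canonical_fixture",
    "summarize",
    "read_catalogue_tsv",
    "write_catalogue_tsv",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
STOP = "X"
_NULL = "."


class CatalogueError(ValueError):
    """Raised for malformed catalogue input."""


class Species(str, Enum):
    HUMAN = "human"
    COW = "cow"
    GOAT = "goat"
    MOUSE = "mouse"


class EventKind(str, Enum):
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    INSERTION = "insertion"
    DELETION = "deletion"


class Zygosity(str, Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    COMPOUND_HETEROZYGOUS = "compound_heterozygous"
    UNKNOWN = "unknown"


class Phenotype(str, Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    UNKNOWN = "unknown"


class Consequence(str, Enum):
    TRUNCATING = "truncating"
    SUBSTITUTION = "substitution"


_NOTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z*])$")


def parse_protein_notation(token: str) -> tuple[str, int, str]:
    """Parse compact protein-change notation like ``W466X`` or ``R182W``.

    Returns ``(reference residue, position, alternate residue)``; the stop
    symbol is normalized to ``'X'`` (``'*'`` accepted on input).  Synonymous
    tokens (reference == alternate) are rejected.
    """
    m = _NOTATION_RE.match(token.strip())
    if m is None:
        raise CatalogueError(f"malformed protein-change token: {token!r}")
    ref, pos_s, alt = m.group(1).upper(), m.group(2), m.group(3).upper()
    if alt == "*":
        alt = STOP
    pos = int(pos_s)
    if ref not in AMINO_ACIDS:
        raise CatalogueError(f"unknown reference residue in token {token!r}")
    if alt not in AMINO_ACIDS and alt != STOP:
        raise CatalogueError(f"unknown alternate residue in token {token!r}")
    if pos < 1:
        raise CatalogueError(f"protein position must be >= 1 in token {token!r}")
    if ref == alt:
        raise CatalogueError(f"synonymous token {token!r} is not a catalogued mutation")
    return ref, pos, alt


@dataclass(frozen=True)
class MutationRecord:
    """One inherited *MANBA* mutation.

    Nucleotide coordinates are stored verbatim from the catalogue source;
    their coordinate system (CDS-relative vs cDNA) is declared by the
    catalogue and bridged to the CDS through an explicit ``coord_offset`` on
    the transcript model, never guessed here.  Protein positions use
    precursor (signal-peptide-included) numbering.
    """

    id: str
    species: Species
    event_kind: EventKind
    protein_ref: str
    protein_pos: int
    protein_alt: str
    nt_start: int | None = None
    nt_end: int | None = None
    inserted_bases: str | None = None
    deleted_bases: str | None = None
    zygosity: Zygosity = Zygosity.UNKNOWN
    observed_phenotype: Phenotype = Phenotype.UNKNOWN
    shared_species: frozenset[Species] = frozenset()
    partner_id: str | None = None  # catalogued second allele of a compound het
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.protein_pos < 1:
            raise CatalogueError(f"{self.id}: protein_pos must be >= 1")
        if self.protein_ref not in AMINO_ACIDS:
            raise CatalogueError(f"{self.id}: invalid protein_ref {self.protein_ref!r}")
        if self.event_kind is EventKind.NONSENSE and self.protein_alt != STOP:
            raise CatalogueError(f"{self.id}: nonsense mutation must have protein_alt 'X'")
        if self.event_kind is EventKind.MISSENSE:
            if self.protein_alt == STOP:
                raise CatalogueError(f"{self.id}: missense mutation cannot introduce a stop")
            if self.protein_alt == self.protein_ref:
                raise CatalogueError(f"{self.id}: synonymous record is not a mutation")
        if self.nt_start is not None and self.nt_start < 1:
            raise CatalogueError(f"{self.id}: nt_start must be >= 1")
        if (
            self.nt_start is not None
            and self.nt_end is not None
            and self.nt_end < self.nt_start
        ):
            raise CatalogueError(f"{self.id}: nt_end < nt_start")
        for bases in (self.inserted_bases, self.deleted_bases):
            if bases is not None and not set(bases) <= set("ACGTN"):
                raise CatalogueError(f"{self.id}: invalid nucleotide string {bases!r}")

    @property
    def is_frameshift(self) -> bool:
        """True when the inserted/deleted base count is not a multiple of 3.

        When the exact bases are unrecorded, an indel annotated with a
        protein-level stop ('X') is conservatively flagged as frameshifting.
        """
        if self.event_kind is EventKind.INSERTION and self.inserted_bases is not None:
            return len(self.inserted_bases) % 3 != 0
        if self.event_kind is EventKind.DELETION and self.deleted_bases is not None:
            return len(self.deleted_bases) % 3 != 0
        if self.event_kind in (EventKind.INSERTION, EventKind.DELETION):
            return self.protein_alt == STOP
        return False

    @property
    def label(self) -> str:
        return f"{self.protein_ref}{self.protein_pos}{self.protein_alt}"


def classify_consequence(record: MutationRecord) -> Consequence:
    """Classify the protein-level consequence of a catalogued mutation.

    Nonsense mutations truncate; insertions and deletions truncate when they
    shift the frame or directly introduce a stop; missense mutations
    substitute one residue.  Total on valid records (every record falls in
    exactly one class).
    """
    if record.event_kind is EventKind.NONSENSE:
        return Consequence.TRUNCATING
    if record.event_kind is EventKind.MISSENSE:
        return Consequence.SUBSTITUTION
    # insertion / deletion
    if record.is_frameshift or record.protein_alt == STOP:
        return Consequence.TRUNCATING
    return Consequence.SUBSTITUTION


@dataclass(frozen=True)
class CatalogueSummary:
    """Per-species consequence counts over a mutation catalogue."""

    total_distinct: int
    per_species_counts: dict[str, int]
    truncating_count: dict[str, int]
    substitution_count: dict[str, int]
    percent_truncating: dict[str, float]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "total_distinct": self.total_distinct,
                "per_species_counts": self.per_species_counts,
                "truncating_count": self.truncating_count,
                "substitution_count": self.substitution_count,
                "percent_truncating": self.percent_truncating,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def summarize(records: Sequence[MutationRecord]) -> CatalogueSummary:
    """Count truncating vs substitution mutations per species.

    ``percent_truncating`` is truncating/total per species, rounded to one
    decimal (e.g. 9 of 13 human mutations -> 69.2).  An empty catalogue gives
    an all-zero summary.
    """
    per_species: dict[str, int] = {}
    trunc: dict[str, int] = {}
    subst: dict[str, int] = {}
    for rec in records:
        sp = rec.species.value
        per_species[sp] = per_species.get(sp, 0) + 1
        if classify_consequence(rec) is Consequence.TRUNCATING:
            trunc[sp] = trunc.get(sp, 0) + 1
        else:
            subst[sp] = subst.get(sp, 0) + 1
    percent = {
        sp: round(100.0 * trunc.get(sp, 0) / n, 1) for sp, n in per_species.items() if n
    }
    return CatalogueSummary(
        total_distinct=len(records),
        per_species_counts=per_species,
        truncating_count={sp: trunc.get(sp, 0) for sp in per_species},
        substitution_count={sp: subst.get(sp, 0) for sp in per_species},
        percent_truncating=percent,
    )


def _rec(
    id: str,
    species: Species,
    kind: EventKind,
    change: str,
    zygosity: Zygosity = Zygosity.UNKNOWN,
    phenotype: Phenotype = Phenotype.UNKNOWN,
    **kw,
) -> MutationRecord:
    ref, pos, alt = parse_protein_notation(change)
    return MutationRecord(
        id=id,
        species=species,
        event_kind=kind,
        protein_ref=ref,
        protein_pos=pos,
        protein_alt=alt,
        zygosity=zygosity,
        observed_phenotype=phenotype,
        **kw,
    )


def canonical_fixture() -> list[MutationRecord]:
    """The fifteen reported beta-mannosidosis mutations (human, goat, cow).

    Human: nine truncating (six nonsense, one frameshifting 10-nt insertion
    producing W192X, two frameshifting deletions) and four missense.  Goat:
    W466X, the same residue also truncated in a mildly affected human
    compound heterozygote (recorded via ``shared_species``).  Cow: W858X,
    which removes only the last 22 residues yet is lethal.  "Lethal"
    ruminant outcomes are recorded as severity class "severe" on the
    three-level scale.
    """
    H, G, C = Species.HUMAN, Species.GOAT, Species.COW
    N, M, I, D = EventKind.NONSENSE, EventKind.MISSENSE, EventKind.INSERTION, EventKind.DELETION
    return [
        _rec("H_E83X", H, N, "E83X", Zygosity.COMPOUND_HETEROZYGOUS, Phenotype.MODERATE,
             partner_id="H_Q426X",
             source_note="biallelic with Q426X on the other chromosome; moderate phenotype"),
        _rec("H_Y126X", H, N, "Y126X", Zygosity.UNKNOWN, Phenotype.SEVERE),
        _rec("H_W192X_ins", H, I, "W192X", Zygosity.UNKNOWN, Phenotype.SEVERE,
             nt_start=562, nt_end=572, inserted_bases="N" * 10,
             source_note="10-nt insertion at the 562-572 loci; frameshift truncates at W192"),
        _rec("H_W231X", H, N, "W231X", Zygosity.UNKNOWN, Phenotype.SEVERE),
        _rec("H_V321X", H, N, "V321X", Zygosity.UNKNOWN, Phenotype.SEVERE),
        _rec("H_Q426X", H, N, "Q426X", Zygosity.COMPOUND_HETEROZYGOUS, Phenotype.MODERATE,
             partner_id="H_E83X",
             source_note="biallelic with E83X on the other chromosome; moderate phenotype"),
        _rec("H_Y485X", H, D, "Y485X", Zygosity.UNKNOWN, Phenotype.SEVERE,
             source_note="frameshifting deletion truncating at Y485"),
        _rec("H_K616X", H, N, "K616X", Zygosity.HETEROZYGOUS, Phenotype.MILD,
             source_note="heterozygote; mild symptoms from age 12 despite loss of W657"),
        _rec("H_V720X", H, D, "V720X", Zygosity.UNKNOWN, Phenotype.SEVERE,
             source_note="frameshifting deletion; loses the last domain and half the "
                         "penultimate domain, destabilizing the fold"),
        _rec("H_R182W", H, M, "R182W", Zygosity.COMPOUND_HETEROZYGOUS, Phenotype.MILD,
             source_note="away from active site; disrupts R182-M416 dipole interaction"),
        _rec("H_G392E", H, M, "G392E", Zygosity.UNKNOWN, Phenotype.MODERATE,
             source_note="close to active site; dislocates the W190-D191-W192 binding motif"),
        _rec("H_S505P", H, M, "S505P", Zygosity.UNKNOWN, Phenotype.SEVERE,
             source_note="breaks the S505-N455 hydrogen bond next to catalytic E457"),
        _rec("H_R641H", H, M, "R641H", Zygosity.HOMOZYGOUS, Phenotype.MODERATE,
             source_note="ruptures the R641-D709 salt bridge; destabilizes the fold"),
        _rec("G_W466X", G, N, "W466X", Zygosity.HOMOZYGOUS, Phenotype.SEVERE,
             shared_species=frozenset({H}),
             source_note="lethal neonatal mannosidosis in Nubian goat; same residue "
                         "truncated in a mild human compound heterozygote"),
        _rec("C_W858X", C, N, "W858X", Zygosity.HOMOZYGOUS, Phenotype.SEVERE,
             source_note="only 22 C-terminal residues missing, yet lethal in cattle"),
    ]


# ---------------------------------------------------------------------------
# TSV dialect: one record per line, header row, '.' for null, UTF-8.
_COLUMNS = [
    "id", "species", "event_kind", "nt_start", "nt_end", "inserted_bases",
    "deleted_bases", "protein_ref", "protein_pos", "protein_alt", "zygosity",
    "observed_phenotype", "shared_species", "partner_id", "source_note",
]


def write_catalogue_tsv(records: Iterable[MutationRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "species": r.species.value,
            "event_kind": r.event_kind.value,
            "nt_start": r.nt_start if r.nt_start is not None else _NULL,
            "nt_end": r.nt_end if r.nt_end is not None else _NULL,
            "inserted_bases": r.inserted_bases or _NULL,
            "deleted_bases": r.deleted_bases or _NULL,
            "protein_ref": r.protein_ref,
            "protein_pos": r.protein_pos,
            "protein_alt": r.protein_alt,
            "zygosity": r.zygosity.value,
            "observed_phenotype": r.observed_phenotype.value,
            "shared_species": ",".join(sorted(s.value for s in r.shared_species)) or _NULL,
            "partner_id": r.partner_id or _NULL,
            "source_note": r.source_note or _NULL,
        })
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalogue_tsv(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise CatalogueError(f"catalogue TSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        def opt(col: str) -> str | None:
            v = row[col]
            return None if v == _NULL or v == "" else v

        shared = opt("shared_species")
        records.append(MutationRecord(
            id=row["id"],
            species=Species(row["species"]),
            event_kind=EventKind(row["event_kind"]),
            nt_start=int(row["nt_start"]) if opt("nt_start") else None,
            nt_end=int(row["nt_end"]) if opt("nt_end") else None,
            inserted_bases=opt("inserted_bases"),
            deleted_bases=opt("deleted_bases"),
            protein_ref=row["protein_ref"],
            protein_pos=int(row["protein_pos"]),
            protein_alt=row["protein_alt"],
            zygosity=Zygosity(row["zygosity"]),
            observed_phenotype=Phenotype(row["observed_phenotype"]),
            shared_species=frozenset(Species(s) for s in shared.split(",")) if shared else frozenset(),
            partner_id=opt("partner_id"),
            source_note=opt("source_note") or "",
        ))
    return records
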