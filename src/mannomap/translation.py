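"""Mutant transcript editing, translation and truncation bookkeeping.

Given a coding sequence and a catalogued nucleotide event, this module applies
the edit, re-selects the open reading frame (first ATG scanning 5'->3' across
all offsets, through the first in-frame stop), translates with the standard
genetic code, and quantifies the protein-level consequence: where the chain
stops, how many wild-type residues are removed, and whether the active-site
residues survive.

Residue numbering is precursor (signal-peptide-included) throughout; mature
numbering is obtained by subtracting the species' signal-peptide length.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, TYPE_CHECKING

from Bio.Seq import Seq

from .catalogue import EventKind, MutationRecord, Consequence, classify_consequence

if TYPE_CHECKING:  # pragma: no cover
    from .structure import ActiveSiteDefinition

__all__ = [
    "TranslationError",
    "TranscriptModel",
    "MutantProteinResult",
    "OpenReadingFrame",
    "Translation",
    "apply_edit",
    "select_reading_frame",
    "translate",
    "truncation_extent",
    "active_site_retained",
    "translate_mutant",
    "result_from_protein_change",
]

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_VALID_BASES = set("ACGT")


class TranslationError(ValueError):
    """Raised for invalid sequences, coordinates or frame selection failures."""


@dataclass(frozen=True)
class TranscriptModel:
    """A wild-type coding sequence with its species bookkeeping.

    ``coord_offset`` bridges catalogue nucleotide coordinates to CDS
    coordinates (catalogue position minus CDS position); it defaults to 0
    (catalogue coordinates are CDS-relative).
    """

    species: str
    cds: str
    signal_peptide_len: int = 17
    coord_offset: int = 0

    def __post_init__(self) -> None:
        cds = self.cds.upper()
        object.__setattr__(self, "cds", cds)
        if len(cds) % 3 != 0:
            raise TranslationError("CDS length must be divisible by 3")
        if not cds.startswith("ATG"):
            raise TranslationError("CDS must begin with ATG")
        if cds[-3:] not in _STOP_CODONS:
            raise TranslationError("CDS must end with a stop codon")
        bad = set(cds) - _VALID_BASES
        if bad:
            raise TranslationError(f"CDS contains non-ACGT characters: {sorted(bad)}")
        if self.signal_peptide_len < 0 or self.signal_peptide_len >= len(cds) // 3 - 1:
            raise TranslationError("signal_peptide_len out of range")

    @property
    def protein(self) -> str:
        """The wild-type protein (precursor, stop excluded)."""
        return translate(self.cds).protein


class OpenReadingFrame(NamedTuple):
    seq: str
    stop_reached: bool


class Translation(NamedTuple):
    protein: str
    stop_reached: bool


@dataclass(frozen=True)
class MutantProteinResult:
    """Protein-level consequence of one mutation.

    ``stop_after_residue`` is the last translated residue in precursor
    numbering (None when the product is full length); ``removed_count`` is
    wild-type length minus retained length; ``retained_fraction`` is the
    retained share of the wild-type chain.  ``active_site_retained`` maps each
    active-site position to whether it is both within the retained chain and
    unmutated; ``active_site_complete`` requires all of them.
    """

    mutant_seq: str
    is_truncated: bool
    stop_after_residue: int | None
    removed_count: int
    retained_fraction: float
    wt_len: int
    non_stop: bool = False  # read-through reached sequence end without a stop
    active_site_retained: dict[int, bool] = field(default_factory=dict)
    active_site_complete: bool | None = None


def apply_edit(cds: str, event: MutationRecord, coord_offset: int = 0) -> str:
    """Apply a single nucleotide event to a coding sequence.

    Catalogue coordinates are converted to 1-based CDS coordinates by
    subtracting ``coord_offset``.  A substitution replaces one base (the
    alternate base is taken from ``inserted_bases`` for point events recorded
    that way, else inferred from the protein change is not attempted — point
    events must carry ``inserted_bases`` of length 1); an insertion inserts
    ``inserted_bases`` after ``nt_start``; a deletion removes the closed
    interval [nt_start, nt_end] and checks ``deleted_bases`` against the
    reference when recorded.
    """
    cds = cds.upper()
    if event.nt_start is None:
        raise TranslationError(f"{event.id}: event has no nucleotide coordinates")
    start = event.nt_start - coord_offset
    if start < 1 or start > len(cds):
        raise TranslationError(f"{event.id}: position {start} outside CDS of length {len(cds)}")

    if event.event_kind is EventKind.INSERTION:
        if not event.inserted_bases:
            raise TranslationError(f"{event.id}: insertion without inserted_bases")
        return cds[:start] + event.inserted_bases.upper() + cds[start:]

    if event.event_kind is EventKind.DELETION:
        end = (event.nt_end - coord_offset) if event.nt_end is not None else start
        if end < start or end > len(cds):
            raise TranslationError(f"{event.id}: deletion interval [{start},{end}] out of bounds")
        removed = cds[start - 1:end]
        if event.deleted_bases and "N" not in event.deleted_bases:
            if removed != event.deleted_bases.upper():
                raise TranslationError(
                    f"{event.id}: deleted_bases {event.deleted_bases!r} do not match "
                    f"reference {removed!r} at {start}-{end}"
                )
        return cds[:start - 1] + cds[end:]

    # point substitution (nonsense or missense at the nucleotide level)
    if not event.inserted_bases or len(event.inserted_bases) != 1:
        raise TranslationError(
            f"{event.id}: point substitution must carry the alternate base in inserted_bases"
        )
    return cds[:start - 1] + event.inserted_bases.upper() + cds[start:]


def select_reading_frame(seq: str) -> OpenReadingFrame:
    """Select the reading frame with methionine as the first residue.

    Scans 5'->3' for the first ATG at any offset and returns the subsequence
    from it through the first in-frame stop codon (inclusive), or to the last
    full codon if no stop is reached (``stop_reached`` False).
    """
    seq = seq.upper()
    if not seq:
        raise TranslationError("empty sequence")
    start = seq.find("ATG")
    if start < 0:
        raise TranslationError("no start codon (ATG) found")
    for i in range(start, len(seq) - 2, 3):
        if seq[i:i + 3] in _STOP_CODONS:
            return OpenReadingFrame(seq[start:i + 3], True)
    trailing = (len(seq) - start) % 3
    end = len(seq) - trailing
    return OpenReadingFrame(seq[start:end], False)


def translate(orf: str) -> Translation:
    """Translate an ORF with the standard genetic code (stop excluded).

    Translation stops at the first in-frame stop codon; ``stop_reached``
    reports whether one was seen.  Non-ACGT characters raise an error naming
    the first offending position (1-based).
    """
    orf = orf.upper()
    if len(orf) < 3:
        raise TranslationError("ORF shorter than one codon")
    if not orf.startswith("ATG"):
        raise TranslationError("ORF must start with ATG")
    for i, base in enumerate(orf):
        if base not in _VALID_BASES:
            raise TranslationError(f"non-ACGT character {base!r} at position {i + 1}")
    trimmed = orf[: len(orf) - len(orf) % 3]
    full = str(Seq(trimmed).translate())  # standard table 1
    stop_idx = full.find("*")
    if stop_idx >= 0:
        return Translation(full[:stop_idx], True)
    return Translation(full, False)


def truncation_extent(wt_len: int, mutant: MutantProteinResult) -> tuple[int, float]:
    """Removed-residue count and retained fraction for a (possibly) truncated chain.

    ``removed_count = wt_len - stop_after_residue``; e.g. the cow W858X chain
    stops after residue 857 of the 879-residue precursor, removing 22.
    """
    stop_after = mutant.stop_after_residue if mutant.stop_after_residue is not None else wt_len
    removed = wt_len - stop_after
    if removed < 0:
        raise TranslationError(
            f"stop_after_residue {stop_after} exceeds wild-type length {wt_len}"
        )
    return removed, stop_after / wt_len


def active_site_retained(
    mutant: MutantProteinResult,
    as_def: "ActiveSiteDefinition",
    wt_seq: str | None = None,
) -> MutantProteinResult:
    """Mark each active-site residue as retained or lost in the mutant chain.

    A position is retained iff it lies at or before the truncation point (or
    the chain is full length) and the residue itself is unmutated.  When both
    the mutant and wild-type sequences are available the residue identity is
    compared directly, which also catches frameshifted (garbled) tails.
    """
    positions = sorted(as_def.all_positions)
    if any(p > mutant.wt_len for p in positions):
        raise TranslationError("active-site position beyond wild-type length")
    retained: dict[int, bool] = {}
    last = mutant.stop_after_residue if mutant.is_truncated else mutant.wt_len
    for pos in positions:
        ok = pos <= (last if last is not None else mutant.wt_len)
        if ok and wt_seq is not None and mutant.mutant_seq:
            if pos <= len(mutant.mutant_seq) and pos <= len(wt_seq):
                ok = mutant.mutant_seq[pos - 1] == wt_seq[pos - 1]
            else:
                ok = False
        retained[pos] = ok
    return replace(
        mutant,
        active_site_retained=retained,
        active_site_complete=all(retained.values()),
    )


def translate_mutant(
    transcript: TranscriptModel,
    event: MutationRecord,
    as_def: "ActiveSiteDefinition | None" = None,
) -> MutantProteinResult:
    """Full consequence pipeline: edit -> frame selection -> translation -> extent.

    The wild-type protein is recomputed from the transcript; the mutant chain
    is compared against it residue by residue.  A read-through that reaches
    the sequence end without a stop is flagged ``non_stop`` and treated as
    truncating at the last full codon (conservative consequence call).
    """
    wt = transcript.protein
    edited = apply_edit(transcript.cds, event, transcript.coord_offset)
    orf = select_reading_frame(edited)
    prot, stop_reached = translate(orf.seq)

    truncated = len(prot) < len(wt)
    non_stop = not stop_reached
    stop_after = len(prot) if truncated else None
    result = MutantProteinResult(
        mutant_seq=prot,
        is_truncated=truncated,
        stop_after_residue=stop_after,
        removed_count=max(len(wt) - len(prot), 0),
        retained_fraction=min(len(prot) / len(wt), 1.0),
        wt_len=len(wt),
        non_stop=non_stop,
    )
    if as_def is not None:
        result = active_site_retained(result, as_def, wt_seq=wt)
    return result


def result_from_protein_change(
    record: MutationRecord,
    wt_len: int,
    as_def: "ActiveSiteDefinition | None" = None,
) -> MutantProteinResult:
    """Build a consequence record from the protein-level annotation alone.

    Used when only the catalogue's protein change is known (no coding
    sequence): a truncating change at residue p stops the chain after p-1;
    a substitution keeps full length but marks position p as mutated.
    """
    if classify_consequence(record) is Consequence.TRUNCATING:
        stop_after = record.protein_pos - 1
        result = MutantProteinResult(
            mutant_seq="",
            is_truncated=True,
            stop_after_residue=stop_after,
            removed_count=wt_len - stop_after,
            retained_fraction=stop_after / wt_len,
            wt_len=wt_len,
        )
    else:
        result = MutantProteinResult(
            mutant_seq="",
            is_truncated=False,
            stop_after_residue=None,
            removed_count=0,
            retained_fraction=1.0,
            wt_len=wt_len,
        )
    if as_def is not None:
        positions = sorted(as_def.all_positions)
        last = result.stop_after_residue if result.is_truncated else wt_len
        retained = {
            pos: pos <= last and not (
                not result.is_truncated and pos == record.protein_pos
            )
            for pos in positions
        }
        result = replace(
            result,
            active_site_retained=retained,
            active_site_complete=all(retained.values()),
        )
    return result
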