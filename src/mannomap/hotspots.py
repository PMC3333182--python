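"""Mutational hot-spot detection on the *MANBA* gene.

Disease mutations cluster along the gene.  A hot-spot segment is a maximal
run of mutations whose consecutive nucleotide positions are no further apart
than a gap threshold; segment boundaries are the positions of the first and
last member mutations.  Five such segments are reported for *MANBA*
(334-375, 544-693, 960-1175, 1363-1541, 1848-2574; lengths 42 to 727).

The numbering system of the reported segment coordinates relative to the CDS
is not fully determined (see docs/methods.md); :func:`residues_covered`
therefore takes an explicit ``coord_offset`` rather than guessing.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "HotspotSegment",
    "REFERENCE_HOTSPOT_RANGES",
    "cluster_mutations",
    "segment_length",
    "residues_covered",
    "write_segments_tsv",
    "write_segments_bed",
]

#: The five reported MANBA hot-spot segments (1-based inclusive nt ranges).
REFERENCE_HOTSPOT_RANGES: tuple[tuple[int, int], ...] = (
    (334, 375),
    (544, 693),
    (960, 1175),
    (1363, 1541),
    (1848, 2574),
)


@dataclass(frozen=True)
class HotspotSegment:
    """A 1-D cluster of mutation nucleotide positions.

    ``start_nt``/``end_nt`` equal the first/last member positions; length is
    inclusive (``end - start + 1``).
    """

    start_nt: int
    end_nt: int
    member_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end_nt < self.start_nt:
            raise ValueError("segment end before start")

    @property
    def length_nt(self) -> int:
        return self.end_nt - self.start_nt + 1


def segment_length(seg: HotspotSegment) -> int:
    """Inclusive nucleotide length of a segment (e.g. 334-375 -> 42)."""
    return seg.length_nt


def cluster_mutations(
    positions: Sequence[tuple[str, int]], gap_threshold: int
) -> list[HotspotSegment]:
    """Group sorted mutation positions into hot-spot segments.

    A new segment starts whenever the gap to the previous position strictly
    exceeds ``gap_threshold`` (a gap exactly equal to the threshold does not
    split).  Input must be sorted ascending by position; each position ends
    up in exactly one segment.
    """
    if not positions:
        raise ValueError("positions must be non-empty")
    if gap_threshold < 1:
        raise ValueError("gap_threshold must be >= 1")
    nts = [p for _, p in positions]
    if any(b < a for a, b in zip(nts, nts[1:])):
        raise ValueError("positions must be sorted ascending by nucleotide")

    segments: list[HotspotSegment] = []
    run: list[tuple[str, int]] = [positions[0]]
    for prev, cur in zip(positions, positions[1:]):
        if cur[1] - prev[1] > gap_threshold:
            segments.append(_segment_from_run(run))
            run = []
        run.append(cur)
    segments.append(_segment_from_run(run))
    return segments


def _segment_from_run(run: list[tuple[str, int]]) -> HotspotSegment:
    return HotspotSegment(
        start_nt=run[0][1],
        end_nt=run[-1][1],
        member_ids=tuple(i for i, _ in run),
    )


def residues_covered(seg: HotspotSegment, coord_offset: int = 0) -> range:
    """Residue positions whose codons intersect the segment.

    Residue r occupies CDS nucleotides [3r-2, 3r]; catalogue coordinates are
    converted by subtracting ``coord_offset``.  Partial codon overlap counts
    the residue as covered.  Returns an inclusive-exclusive ``range`` of
    residue positions.
    """
    start = seg.start_nt - coord_offset
    end = seg.end_nt - coord_offset
    if start < 1:
        raise ValueError("coord_offset puts segment start below position 1")
    first = (start + 2) // 3  # residue containing start
    last = (end + 2) // 3
    return range(first, last + 1)


def write_segments_tsv(segments: Sequence[HotspotSegment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "start_nt": s.start_nt,
                "end_nt": s.end_nt,
                "length_nt": s.length_nt,
                "n_members": len(s.member_ids),
                "member_ids": ",".join(s.member_ids),
            }
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)


def write_segments_bed(
    segments: Sequence[HotspotSegment], path: str | Path, chrom: str = "MANBA"
) -> None:
    """BED output; the 1-based inclusive ranges are converted to 0-based
    half-open intervals here at the writer boundary only."""
    with open(path, "w") as fh:
        for i, s in enumerate(segments, 1):
            fh.write(f"{chrom}\t{s.start_nt - 1}\t{s.end_nt}\thotspot_{i}\n")
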