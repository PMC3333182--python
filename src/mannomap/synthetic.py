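"""Deterministic synthetic fixtures: toy transcripts, planted mutation
clusters, and 3-D pseudo-structures with an active-site pocket at known
distances.

Every generator is bit-reproducible from ``(seed, spec)`` and emits the same
types the real-data readers produce, so every pipeline stage can be exercised
without downloads.  These fixtures emulate the *shape* of the real inputs
(a signal-peptide-bearing CDS, a mutation catalogue with 1-D cluster
structure, a folded chain with a deep active-site pocket); they do not
emulate realistic codon usage, protein geometry or energetics.

:func:`reference_fixtures` additionally bundles the in-catalogue literature
data: the 15-mutation catalogue, the five reported hot-spot segments, and the
human active-site definition.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .catalogue import (
    EventKind,
    MutationRecord,
    Species,
    canonical_fixture,
)
from .hotspots import REFERENCE_HOTSPOT_RANGES, HotspotSegment
from .structure import ActiveSiteDefinition, Atom, Residue, StructureModel, human_active_site
from .translation import TranscriptModel, translate

__all__ = [
    "SyntheticSpec",
    "generate_transcript",
    "plant_mutations",
    "generate_structure",
    "reference_fixtures",
]

_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_NON_MET_CODONS = [c for c in _CODONS if c != "ATG"]
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``planted_clusters`` is a list of (start_nt, end_nt, n_mutations); the
    generator spaces mutations within each cluster at most
    ``intra_cluster_gap`` apart and demands inter-cluster gaps strictly
    larger, so gap-threshold clustering at that gap recovers the planted
    partition exactly.  ``probe_distances`` places designated residues at
    exact recorded distances (A) from the active-site pocket.
    """

    seed: int = 0
    n_residues: int = 120
    signal_len: int = 17
    active_site_positions: frozenset[int] = frozenset({40, 41, 42, 60, 75, 80, 95})
    planted_clusters: tuple[tuple[int, int, int], ...] = ()
    intra_cluster_gap: int = 30
    pocket_radius_A: float = 4.0
    decoy_distance_A: float = 25.0
    probe_distances: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_residues < self.signal_len + 10:
            raise ValueError("n_residues must be >= signal_len + 10")
        if any(p < 1 or p > self.n_residues for p in self.active_site_positions):
            raise ValueError("active-site positions outside protein length")
        prev_end = None
        for start, end, n in self.planted_clusters:
            if end < start or n < 1:
                raise ValueError(f"invalid cluster ({start},{end},{n})")
            if prev_end is not None and start - prev_end <= self.intra_cluster_gap:
                raise ValueError("planted clusters closer than intra_cluster_gap")
            if n > 1 and (end - start) // (n - 1) > self.intra_cluster_gap:
                raise ValueError(
                    f"cluster ({start},{end}) too sparse for {n} mutations at "
                    f"gap {self.intra_cluster_gap}"
                )
            prev_end = end

    @property
    def active_site(self) -> ActiveSiteDefinition:
        cat = frozenset(sorted(self.active_site_positions)[:2])
        return ActiveSiteDefinition(
            catalytic=cat, binding=self.active_site_positions - cat
        )


def generate_transcript(spec: SyntheticSpec, species: str = "human") -> tuple[TranscriptModel, str]:
    """A random valid CDS and its protein: ATG + non-stop codons + stop.

    CDS length is ``3 * (n_residues + 1)`` (stop included); the protein has
    exactly ``n_residues`` residues starting with methionine, and
    ``translate(cds)`` reproduces it (round-trip invariant).
    """
    rng = np.random.default_rng(spec.seed)
    body = rng.choice(_NON_MET_CODONS, size=spec.n_residues - 1)
    stop = rng.choice(["TAA", "TAG", "TGA"])
    cds = "ATG" + "".join(body) + str(stop)
    transcript = TranscriptModel(
        species=species, cds=cds, signal_peptide_len=spec.signal_len
    )
    protein = translate(cds).protein
    assert len(protein) == spec.n_residues
    return transcript, protein


def plant_mutations(spec: SyntheticSpec, transcript: TranscriptModel) -> list[MutationRecord]:
    """Mutation records planted at known positions with known cluster structure.

    Within each planted cluster, positions are evenly spaced (consecutive
    gaps <= ``intra_cluster_gap``); event kinds cycle through nonsense,
    missense, insertion and deletion.  Insertions get a random non-multiple-
    of-3 base count (frameshifting); nonsense records carry the wild-type
    residue at the affected codon.
    """
    rng = np.random.default_rng(spec.seed + 1)
    protein = transcript.protein
    cds = transcript.cds
    cds_len = len(cds)
    records: list[MutationRecord] = []
    kinds = [EventKind.NONSENSE, EventKind.MISSENSE, EventKind.INSERTION, EventKind.DELETION]
    counter = 0
    for ci, (start, end, n) in enumerate(spec.planted_clusters):
        if end > cds_len:
            raise ValueError(f"cluster ({start},{end}) outside CDS of length {cds_len}")
        if n == 1:
            positions = [start]
        else:
            positions = [round(start + k * (end - start) / (n - 1)) for k in range(n)]
            positions[0], positions[-1] = start, end
        for nt in positions:
            kind = kinds[counter % len(kinds)]
            counter += 1
            records.append(_plant_one(rng, transcript, ci, nt, kind))
    return records


def _single_base_edits(cds: str, nt: int) -> list[tuple[str, str]]:
    """(alt base, new codon) for every substitution at CDS position nt."""
    codon_start = 3 * ((nt - 1) // 3)
    within = (nt - 1) % 3
    codon = cds[codon_start:codon_start + 3]
    out = []
    for base in "ACGT":
        if base != cds[nt - 1]:
            out.append((base, codon[:within] + base + codon[within + 1:]))
    return out


def _plant_one(
    rng: np.random.Generator, transcript: TranscriptModel, ci: int, nt: int, kind: EventKind
) -> MutationRecord:
    """One honest nucleotide event at position nt.

    A nonsense event is only planted where a single-base change truly creates
    a stop codon; otherwise the kind falls back to missense, and to a
    frameshifting single-base deletion when every substitution at the site is
    synonymous or stop-creating.
    """
    cds, protein = transcript.cds, transcript.protein
    res_pos = min((nt + 2) // 3, len(protein))
    ref = protein[res_pos - 1]
    common = dict(id=f"syn_c{ci}_{nt}", species=Species(transcript.species),
                  nt_start=nt, protein_ref=ref, protein_pos=res_pos)
    stops = {"TAA", "TAG", "TGA"}

    if kind is EventKind.INSERTION:
        n_ins = int(rng.choice([1, 2, 4, 5, 7, 10]))  # never a multiple of 3
        bases = "".join(rng.choice(list("ACGT"), size=n_ins))
        return MutationRecord(event_kind=kind, inserted_bases=bases, protein_alt="X", **common)

    if kind is EventKind.DELETION:
        n_del = int(rng.choice([1, 2, 4]))
        end_nt = min(nt + n_del - 1, len(cds))
        return MutationRecord(event_kind=kind, nt_end=end_nt,
                              deleted_bases=cds[nt - 1:end_nt], protein_alt="X", **common)

    edits = _single_base_edits(cds, nt)
    if kind is EventKind.NONSENSE:
        for base, codon in edits:
            if codon in stops:
                return MutationRecord(event_kind=kind, inserted_bases=base,
                                      protein_alt="X", **common)
        kind = EventKind.MISSENSE  # no single-base stop reachable here

    for base, codon in edits:
        alt = translate("ATG" + codon + "TAA").protein[1:]
        if codon not in stops and alt and alt != ref:
            return MutationRecord(event_kind=EventKind.MISSENSE, inserted_bases=base,
                                  protein_alt=alt, **common)
    # every substitution is synonymous or stop-creating: frameshift instead
    return MutationRecord(event_kind=EventKind.DELETION, nt_end=nt,
                          deleted_bases=cds[nt - 1], protein_alt="X", **common)


def generate_structure(
    spec: SyntheticSpec, protein: str, max_retries: int = 2000
) -> tuple[StructureModel, dict[int, float]]:
    """A one-pseudo-atom-per-residue structure with a planted pocket.

    Active-site residues sit inside a sphere of radius ``pocket_radius_A``
    around the origin.  Each probe residue in ``spec.probe_distances`` is
    placed so that its minimal distance to the active site equals the
    requested value exactly (anchored beyond the pocket atom with the
    largest x-coordinate).  All remaining residues follow a self-avoiding
    random walk far from the pocket.  Returns the model and the ground-truth
    probe distances.
    """
    rng = np.random.default_rng(spec.seed + 2)
    n = len(protein)
    as_positions = sorted(spec.active_site_positions)
    probes = dict(spec.probe_distances)
    if set(probes) & set(as_positions):
        raise ValueError("probe residues cannot be active-site residues")

    coords: dict[int, np.ndarray] = {}
    # pocket atoms, unique maximal x for the anchor
    for attempt in range(max_retries):
        dirs = rng.normal(size=(len(as_positions), 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = spec.pocket_radius_A * rng.uniform(size=(len(as_positions), 1)) ** (1 / 3)
        pts = dirs * radii  # uniform in the pocket sphere
        pts = pts[np.argsort(pts[:, 0])]
        if (np.diff(pts[:, 0]) > 1e-6).all():
            break
    else:  # pragma: no cover - bounded-retry guard
        raise RuntimeError("could not place pocket atoms")
    for pos, pt in zip(as_positions, pts):
        coords[pos] = pt
    anchor = pts[-1]  # strictly largest x among pocket atoms

    truth: dict[int, float] = {}
    for pos, d in sorted(probes.items()):
        # beyond the largest-x pocket atom along +x: the minimum over pocket
        # atoms is attained at the anchor and equals d exactly
        coords[pos] = anchor + np.array([d, 0.0, 0.0])
        truth[pos] = float(d)

    # self-avoiding walk for the remaining residues, kept away from pocket
    walk_start = np.array([60.0, 0.0, 0.0])
    prev = walk_start
    placed = list(coords.values())
    for pos in range(1, n + 1):
        if pos in coords:
            continue
        for attempt in range(max_retries):
            step = rng.normal(size=3)
            step = 3.8 * step / np.linalg.norm(step)
            cand = prev + step
            if np.linalg.norm(cand) < 45.0:  # exclusion zone around the pocket
                continue
            if placed and min(np.linalg.norm(cand - p) for p in placed) < 2.0:
                continue
            break
        else:  # pragma: no cover
            raise RuntimeError(f"could not place residue {pos} after {max_retries} retries")
        coords[pos] = cand
        prev = cand
        placed.append(cand)

    residues = tuple(
        Residue(
            number=pos,
            name=_AA3.get(protein[pos - 1], "GLY"),
            atoms=(Atom("CA", "C", tuple(map(float, coords[pos]))),),
        )
        for pos in range(1, n + 1)
    )
    return StructureModel(chain_id="A", residues=residues), truth


def reference_fixtures() -> tuple[list[MutationRecord], list[HotspotSegment], ActiveSiteDefinition]:
    """The bundled literature data, ready for the pipeline.

    Returns the 15-record mutation catalogue, the five reported *MANBA*
    hot-spot segments (verbatim boundaries), and the seven-residue human
    active-site definition.
    """
    segments = [HotspotSegment(start_nt=a, end_nt=b) for a, b in REFERENCE_HOTSPOT_RANGES]
    return canonical_fixture(), segments, human_active_site()
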