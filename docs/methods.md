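# Methods

## Problem and model

Lysosomal β-D-mannosidase (the *MANBA* gene product) removes the final
β-linked mannose from N-linked glycans. Its deficiency — β-mannosidosis —
behaves very differently across species: uniformly lethal neonatal disease
in goat and cow, mild-to-severe presentations in human. `mannomap`
operationalizes a structural explanation of that spread as a deterministic,
testable pipeline with five stages: catalogue → protein-level consequence →
active-site proximity → severity call → gene-level hot-spots, plus
cross-species transfer of observed mutations.

The underlying model is that of a single-chain, multi-domain enzyme whose
active site combines two catalytic nucleophiles (E457, E554, in the TIM
barrel) with five substrate-gripping residues (W190, D191, W192 on an
extended loop; W390 and W657 on loops adjacent to E457). Severity follows
from three observations: (i) a truncation that removes any active-site
residue cannot form a working enzyme; (ii) the C-terminal domain stabilizes
the fold, so even near-full-length truncations and fold-destabilizing
substitutions are harmful; (iii) phenotype is modulated by genotype
(recessive inheritance — one functional allele rescues) and by species
(chitobiase, an exoglycosidase highly expressed in human and rodents but not
in ruminants, partially compensates for β-mannosidase loss).

## Residue numbering

Precursor (signal-peptide-included, UniProt-style) numbering is canonical
throughout the catalogue, the active-site definition and all results. Mature
numbering (used by alignment rows, which hold signal-trimmed sequences) is
precursor − signal length; signal peptides are 17 aa in human/cow/goat and
19 aa in mouse. The species table records precursor lengths (879 aa for the
human and cow enzymes — the cow length is what makes W858X remove exactly
22 residues).

## Catalogue and consequence calls

A `MutationRecord` stores the nucleotide event verbatim (1-based, coordinate
system declared by the catalogue; an explicit `coord_offset` bridges to CDS
coordinates, default 0) and the protein change in `<ref><pos><alt>` notation
with `X` as the stop symbol (`*` normalized on input). Consequence is a
total, two-way partition: nonsense → truncating; insertion/deletion →
truncating when frameshifting (base count ≢ 0 mod 3) or stop-introducing;
missense → substitution.

The bundled catalogue has 15 records: 13 human (9 truncating — six
nonsense, the 10-nt insertion at loci 562–572 producing W192X, and two
frameshifting deletions (Y485X, V720X) — plus 4 missense), the goat W466X
(shared with a human compound heterozygote) and the cow W858X. Two counts of
the human total circulate in the literature (13 vs 14, depending on whether
W466X is counted as a human allele); the catalogue uses the 13-human reading,
which is the only one consistent with "9 of 13 truncating" and four missense.
The biallelic E83X/Q426X patient is represented by cross-referencing
`partner_id` fields.

## Mutant translation

Edits are applied literally to the CDS (substitution, insertion after the
stated position, deletion of a closed interval with reference checking);
frame re-selection scans 5′→3′ for the first ATG at any offset and reads
through the first in-frame stop; translation uses the standard genetic code
(the nuclear *MANBA* transcript; no alternative table is plausible). A
read-through that reaches the sequence end without a stop is flagged
`non_stop` and treated as truncating at the last full codon — a conservative
consequence call for an abnormal product. Truncation extent is plain
bookkeeping: `removed = L_wt − stop_after`, `retained = stop_after / L_wt`.
Active-site retention requires the position to lie within the retained chain
*and* be unmutated; when sequences are available the residue identities are
compared directly, which also catches garbled frameshift tails.

When only the protein-level annotation is known (no CDS), a truncating
change at residue p is modeled as stopping after p − 1. This is exact for
nonsense mutations and the convention used for the catalogued frameshifts,
whose stop position is reported at the affected residue.

## Structure analysis

Distances are minimal heavy-atom distances (hydrogens are absent from
models and X-ray templates and are dropped at parse time; waters ignored).
Distance to the active site is the minimum over the seven members, ties
broken toward the lower residue number. Defaults, all configurable:

| parameter | default | meaning |
|---|---|---|
| `proximity_A` | 8.0 Å | "close to active site" (boundary inclusive) |
| `direct_interaction_A` | 4.5 Å | direct active-site interaction |
| `salt_bridge_A` | 4.0 Å | basic-N to acidic-O cutoff |
| `hbond_A` | 3.5 Å | donor–acceptor heavy-atom cutoff |
| `catalytic_adjacency` | 2 | sequence distance counting as "next to" a nucleophile |
| `last_domain_boundary` | residue 720 | C-terminal stabilizing-domain start |
| `gap_threshold_nt` | 150 | hot-spot split gap |

The 8 Å proximity default separates the known "close" exemplars (G392,
S505) from the "away" ones (R182, R641) on any reasonable model; no
published quantitative threshold exists, which is why it is a config key.
Contact detection is deliberately distance-only (no angular terms): the
substitution rationales it supports argue from proximity diagrams, not
geometry-validated bonds. The domain boundary at residue 720 is anchored on
V720X, which removes the entire last domain and half the penultimate one;
domain boundaries are not published numerically, so the value is
configurable.

## Severity rules

Rule order is **structural base class → zygosity → species**:

1. *Truncations*: severe if any active-site residue is lost **or**
   `stop_after < 720`; else moderate (short C-terminal tail).
2. *Substitutions*: severe on direct active-site interaction (measured
   d ≤ 4.5 Å, a stated "direct" location, or a lost contact to a residue
   within ±2 of a catalytic nucleophile — the S505P/N455/E457 case);
   moderate when close (d ≤ 8 Å) or when a fold-stabilizing contact (salt
   bridge / H-bond) is lost; mild otherwise.
3. *Zygosity*: a genotype whose second allele is functional or uncatalogued
   (simple heterozygote; compound heterozygote with unknown partner) is
   classed mild — in a recessive disorder one intact allele suffices, and in
   human chitobiase adds slack. A compound heterozygote whose partner is a
   catalogued deleterious allele (E83X/Q426X) is scored from the more severe
   allele and attenuated exactly one level (floor mild).
4. *Species*: without chitobiase rescue (cow, goat) any truncation, and any
   structure-affecting substitution, escalates to severe — "lethal" collapses
   onto severe on the three-level scale.

The classifier is total and deterministic; every call carries rationale
codes and the evidence values used. With the bundled catalogue and the
literature-stated structural evidence for the four substitutions, all 15
calls match the observed phenotypes, including the instructive pairs
(goat W466X severe vs human W466X compound-het mild; cow W858X severe vs
the same truncation being moderate under human rules).

Substitution evidence can be a measured distance, a qualitative location
class, or both; the four bundled evidence records use the qualitative
classes stated in the clinical/structural literature rather than invented
distances. A substitution with no evidence at all falls back to
sequence-only rules (active-site or catalytic-adjacent position → severe,
else mild) with a logged warning.

## Hot-spots

Clustering is a single pass over sorted nucleotide positions: split where
the gap strictly exceeds the threshold (a gap equal to the threshold does
not split); segment boundaries are the first/last member positions and
lengths are inclusive. No published gap threshold exists; the default
(150 nt) is a modeling choice the user can override — necessarily so, since
the reported between-segment gap of 169 nt (375→544) is smaller than the
largest segment span (727 nt), meaning no single threshold is "the" right
one. Codon coverage counts a residue if its codon [3r−2, 3r] intersects the
segment at all (partial overlap counts).

Known discrepancy: under `coord_offset = 0` (CDS coordinates) the codon of
E554 is 1660–1662, which falls in none of the five reported segments, while
the reported segments are said to cover both catalytic nucleophiles. The
numbering system of the published segment coordinates (CDS vs cDNA with
UTR) therefore cannot be pinned down; the module computes coverage for any
user-supplied offset and makes no guess. The same applies to the 562–572
insertion loci vs the codon arithmetic of W192 (codon 574–576), which is why
`coord_offset` is exposed on the transcript model.

## Synthetic data

The generators are part of the public contract and are bit-reproducible
from `(seed, spec)` using one documented PRNG (`numpy.random.default_rng`):

- *Transcripts*: ATG + (n−1) random non-stop codons + stop; translation
  round-trips to the stored protein by construction.
- *Mutation sets*: evenly spaced positions inside each planted cluster
  (consecutive gaps ≤ the intra-cluster gap, inter-cluster gaps strictly
  larger), so gap clustering at that gap recovers the planted partition
  exactly — a recovery property the acceptance script measures at 100%.
  Events are honest nucleotide edits: a nonsense record is only planted
  where a single-base change truly creates a stop codon (with missense and
  frameshift-deletion fallbacks), so synthetic catalogues flow through
  `apply_edit`/`translate_mutant` like real ones.
- *Structures*: one pseudo-atom (alpha-carbon-like center) per residue;
  active-site residues sampled uniformly inside a pocket sphere
  (default radius 4 Å); each probe residue placed beyond the pocket atom
  with the largest x-coordinate, which makes its minimal distance to the
  active site *exactly* the requested value; all other residues follow a
  self-avoiding random walk excluded from a 45 Å zone around the pocket.
  Full side-chain geometries for contact tests are constructed directly in
  the tests.

What passing on synthetic data does **not** show: the generators emulate
the shape of the real inputs, not their content — no realistic codon usage,
no real fold, no energetics, no splice structure. They validate the
arithmetic and the rules, not the biology; the biology enters through the
bundled catalogue, active-site definition and literature-stated structural
evidence, which the classifier reproduces.

## Problem sizes and numerics

The test suite and acceptance script run at deliberately small scale —
100-residue toy transcripts, 4-residue random structures with ≤4 atoms,
100 seeded trials per stochastic property — chosen because every property
checked (distance equivalence to a brute-force scan at ≤1e−9 Å, rigid-body
invariance, cluster recovery, translation round-trip) is scale-free.
Distances use `scipy.spatial.distance.cdist` minima; proximity boundaries
are inclusive; the severity scale is ordered mild < moderate < severe and
all rule evaluations are pure functions of their inputs.

## Limitations

- Severity rules are calibrated on fifteen mutations; they encode the
  published case narratives, not a fitted statistical model, and should be
  read as a structured hypothesis.
- Zygosity handling needs a catalogued partner allele to distinguish a
  biallelic deleterious genotype from a carrier-like one; unknown partners
  default to the lenient reading.
- Structural evidence for the four substitutions is qualitative; with real
  coordinate models the same rules run off measured distances and detected
  contacts instead.
- Homology model building, stereochemical validation, RMSD, secondary
  structure and splice variants are out of scope.
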