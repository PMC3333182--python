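# mannomap

Genotype–phenotype analysis of inherited mutations in *MANBA*, the gene
encoding lysosomal β-D-mannosidase. Loss of this glycosyl hydrolase causes
β-mannosidosis, a rare autosomal-recessive lysosomal storage disorder that is
lethal in ruminants but ranges from mild to severe in humans. `mannomap` is a
library (plus a thin CLI) for the structural-bioinformatics workflow that
connects a mutation catalogue to predicted disease severity:

- **Catalogue** — a typed data model for inherited mutations
  (`W466X`, `R182W`, …) with TSV round-trip I/O and per-species summary
  statistics. The bundled catalogue holds the fifteen reported
  β-mannosidosis mutations (13 human, 1 goat, 1 cow); truncations make up
  ≈70% of the human alleles (9/13).
- **Mutant translation** — applies nucleotide events to a CDS, re-selects the
  reading frame (first ATG, 5′→3′), translates with the standard genetic
  code, and quantifies the truncation: stop position, removed residues
  (`removed = L_wt − stop_after`), retained fraction, and survival of the
  seven active-site residues (catalytic nucleophiles **E457, E554**; binding
  residues **W190, D191, W192, W390, W657**; precursor numbering).
- **Structure analysis** — PDB reading, minimal heavy-atom residue–residue
  distances, distance-to-active-site with a close/away call
  (d ≤ 8 Å ⇒ close, configurable), and distance-only salt-bridge
  (N⁺···O⁻ ≤ 4.0 Å) and hydrogen-bond (N/O···N/O ≤ 3.5 Å) detection.
- **Severity rules** — a deterministic three-level classifier
  (mild/moderate/severe) with machine-readable rationale codes: truncations
  losing active-site residues or the C-terminal stabilizing domain are
  severe; substitutions are ranked by active-site proximity and lost
  stabilizing contacts; heterozygous genotypes attenuate; ruminants (no
  chitobiase rescue) escalate.
- **Cross-species extrapolation** — profile-alignment position mapping
  between human, cow, goat and mouse (mature numbering, signal peptides of
  17 aa / 19 aa in mouse), with Clustal-style column conservation classes.
- **Hot-spots** — gap-threshold clustering of mutation positions along the
  gene; the five reported *MANBA* segments (334–375 … 1848–2574) span 42 to
  727 nt.
- **Synthetic data** — seeded generators for toy transcripts, mutation
  catalogues with planted cluster structure, and 3-D pseudo-structures with
  an active-site pocket at exactly known distances, so every stage is
  testable offline.

## Worked example

```python
from mannomap import canonical_fixture
from mannomap.severity import classify_all, reported_substitution_evidence

records = canonical_fixture()
calls = classify_all(records, evidence=reported_substitution_evidence())
for rid in sorted(calls):
    print(rid, calls[rid].klass, calls[rid].rationale)
```

Running `python examples/03_severity_calls.py` prints (abridged):

```
C_W858X      predicted=severe   observed=severe   OK   [TRUNC_SMALL_TAIL, RUMINANT_NO_CHITOBIASE]
H_K616X      predicted=mild     observed=mild     OK   [TRUNC_LOSES_ACTIVE_SITE, TRUNC_LAST_DOMAIN_LOSS, HET_ATTENUATED]
H_S505P      predicted=severe   observed=severe   OK   [SUBST_DIRECT_AS_INTERACTION]
...
15/15 predictions match the observed phenotype
```

The cow W858X call illustrates the species modifier: the truncation removes
only 22 of 879 precursor residues (`TRUNC_SMALL_TAIL`) yet is lethal in
cattle because ruminants lack chitobiase compensation. K616X removes
active-site residue W657 — severe at base — but the heterozygous carrier is
classed mild. S505P breaks the hydrogen bond to N455, the residue next to
catalytic nucleophile E457, and is severe.

The other examples (`examples/01…06`) cover catalogue summaries, frameshift
translation, hot-spot clustering, cross-species extrapolation (e.g. human
Q426 maps to a non-conserved proline in goat) and planted-distance recovery
on synthetic structures.

A thin CLI wraps the same functions:

```bash
mannomap summary
mannomap classify
mannomap hotspots --positions m1:334,m2:375,m3:544 --gap-threshold 150
mannomap run-all --out results/
```

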