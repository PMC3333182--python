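"""Cross-species extrapolation of observed mutations.

Maps every human mutation to its homologous goat position through a
four-species profile alignment (here, a synthetic stand-in with the known
cross-species differences planted), reporting the goat wild-type residue and
the Clustal-style conservation class of each column.  Note Q426, whose goat
homolog is P — one of the few non-conserved mutation sites.
"""
from mannomap import canonical_fixture, extrapolate_mutations
from mannomap.catalogue import Species
from mannomap.pipeline import synthetic_reference_alignment

records = [r for r in canonical_fixture() if r.species is Species.HUMAN]
aln = synthetic_reference_alignment(seed=0)

for row in extrapolate_mutations(records, aln, "goat"):
    print(f"{row.origin_id:12s} human pos {row.origin_pos:3d} -> goat pos "
          f"{row.target_pos} ({row.target_wt_residue}, {row.conserved})")
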