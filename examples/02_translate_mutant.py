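"""Apply a frameshifting insertion to a coding sequence and translate it.

Builds a 120-residue synthetic transcript, inserts two bases inside codon 30,
and reports where the shifted reading frame hits a premature stop — the same
consequence call made for the catalogued frameshift truncations.
"""
from mannomap import MutationRecord, EventKind, Species, translate_mutant
from mannomap.synthetic import SyntheticSpec, generate_transcript

spec = SyntheticSpec(seed=7, n_residues=120)
transcript, wild_type = generate_transcript(spec)

event = MutationRecord(
    id="demo_fs", species=Species.HUMAN, event_kind=EventKind.INSERTION,
    nt_start=88, inserted_bases="AC",  # 2-nt insertion inside codon 30
    protein_ref=wild_type[29], protein_pos=30, protein_alt="X",
)
result = translate_mutant(transcript, event, spec.active_site)

print(f"wild-type length: {len(wild_type)} residues")
print(f"mutant truncated: {result.is_truncated}")
print(f"chain stops after residue: {result.stop_after_residue}")
print(f"residues removed: {result.removed_count} "
      f"(retained fraction {result.retained_fraction:.2f})")
print(f"active site complete: {result.active_site_complete}")
# The retained prefix is wild type; everything after the insertion is garbled
# until the new frame reaches a stop codon.
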