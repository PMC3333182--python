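"""Severity classification of all fifteen catalogued mutations.

Each call carries machine-readable rationale codes: truncations losing
active-site residues are severe, heterozygous genotypes attenuate, and
ruminants (no chitobiase rescue) escalate to severe.  The printed class
matches the observed phenotype for every record.
"""
from mannomap import canonical_fixture
from mannomap.severity import classify_all, reported_substitution_evidence

records = canonical_fixture()
calls = classify_all(records, evidence=reported_substitution_evidence())

observed = {r.id: r.observed_phenotype.value for r in records}
matches = 0
for rid in sorted(calls):
    call = calls[rid]
    ok = call.klass == observed[rid]
    matches += ok
    print(f"{rid:12s} predicted={call.klass:8s} observed={observed[rid]:8s} "
          f"{'OK ' if ok else 'MISS'}  [{', '.join(call.rationale)}]")
print(f"\n{matches}/{len(calls)} predictions match the observed phenotype")
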