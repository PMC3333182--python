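"""Severity rules: truncations, substitutions, zygosity and species modifiers."""
import dataclasses
import itertools

import pytest

from mannomap.catalogue import EventKind, MutationRecord, Species, Zygosity
from mannomap.config import Thresholds
from mannomap.severity import (
    ContactLoss,
    SeverityError,
    StructuralEvidence,
    classify_all,
    classify_substitution,
    classify_truncation,
    reported_substitution_evidence,
)
from mannomap.structure import human_active_site
from mannomap.translation import result_from_protein_change

AS = human_active_site()


def _trunc_record(change, species=Species.HUMAN, zygosity=Zygosity.UNKNOWN, **kw):
    from mannomap.catalogue import parse_protein_notation
    ref, pos, alt = parse_protein_notation(change)
    return MutationRecord(id=f"t_{change}", species=species, event_kind=EventKind.NONSENSE,
                          protein_ref=ref, protein_pos=pos, protein_alt=alt,
                          zygosity=zygosity, **kw)


def _subst_record(change, zygosity=Zygosity.UNKNOWN, species=Species.HUMAN):
    from mannomap.catalogue import parse_protein_notation
    ref, pos, alt = parse_protein_notation(change)
    return MutationRecord(id=f"s_{change}", species=species, event_kind=EventKind.MISSENSE,
                          protein_ref=ref, protein_pos=pos, protein_alt=alt,
                          zygosity=zygosity)


def _call_trunc(record, wt_len=879, catalogue=None):
    mutant = result_from_protein_change(record, wt_len, AS)
    return classify_truncation(record, mutant, catalogue=catalogue)


class TestClassifyTruncation:
    def test_goat_homozygous_truncation_is_severe(self):
        rec = _trunc_record("W466X", species=Species.GOAT, zygosity=Zygosity.HOMOZYGOUS)
        assert _call_trunc(rec).klass == "severe"

    def test_human_compound_het_with_unknown_partner_is_mild(self):
        rec = _trunc_record("W466X", zygosity=Zygosity.COMPOUND_HETEROZYGOUS)
        assert _call_trunc(rec).klass == "mild"

    def test_v720x_loses_last_domain_severe(self):
        rec = _trunc_record("V720X", zygosity=Zygosity.HOMOZYGOUS)
        call = _call_trunc(rec)
        assert call.klass == "severe"
        assert "TRUNC_LAST_DOMAIN_LOSS" in call.rationale

    def test_cow_small_tail_still_severe_without_chitobiase(self):
        rec = _trunc_record("W858X", species=Species.COW, zygosity=Zygosity.HOMOZYGOUS)
        call = _call_trunc(rec)
        assert call.klass == "severe"
        assert "RUMINANT_NO_CHITOBIASE" in call.rationale
        assert call.evidence["stop_after_residue"] == 857

    def test_human_small_tail_would_be_moderate(self):
        rec = _trunc_record("W858X", zygosity=Zygosity.HOMOZYGOUS)
        assert _call_trunc(rec).klass == "moderate"

    def test_missense_input_rejected(self):
        rec = _subst_record("R182W")
        mutant = result_from_protein_change(rec, 879, AS)
        with pytest.raises(SeverityError):
            classify_truncation(rec, mutant)


class TestClassifySubstitution:
    @pytest.mark.parametrize(
        "rid,expected",
        [("H_R182W", "mild"), ("H_G392E", "moderate"),
         ("H_S505P", "severe"), ("H_R641H", "moderate")],
    )
    def test_reported_evidence_reproduces_observed_classes(self, records_by_id, rid, expected):
        rec = records_by_id[rid]
        ev = reported_substitution_evidence()[rid]
        call = classify_substitution(
            rec, contacts_lost=ev.contacts_lost, location=ev.location,
            catalogue=records_by_id,
        )
        assert call.klass == expected

    def test_contact_adjacent_to_catalytic_nucleophile_is_direct(self):
        # losing a bond to N455 (two residues from E457) disturbs the nucleophile
        rec = _subst_record("S505P")
        call = classify_substitution(
            rec, contacts_lost=[ContactLoss(455, "hbond")], location="away"
        )
        assert call.klass == "severe"
        assert "SUBST_DIRECT_AS_INTERACTION" in call.rationale

    def test_measured_distance_drives_class(self):
        rec = _subst_record("G392E")
        assert classify_substitution(rec, distance_to_AS=3.0).klass == "severe"
        assert classify_substitution(rec, distance_to_AS=6.0).klass == "moderate"
        assert classify_substitution(rec, distance_to_AS=20.0).klass == "mild"

    def test_distance_monotonicity(self):
        # decreasing distance never decreases severity, other evidence fixed
        rec = _subst_record("G392E")
        order = {"mild": 0, "moderate": 1, "severe": 2}
        last = 2
        for d in (0.0, 2.0, 4.5, 4.6, 8.0, 8.1, 15.0, 40.0):
            k = order[classify_substitution(rec, distance_to_AS=d).klass]
            assert k <= last
            last = k

    def test_truncating_input_rejected(self):
        rec = _trunc_record("W466X")
        with pytest.raises(SeverityError):
            classify_substitution(rec)


class TestZygosityRules:
    def test_known_partner_attenuates_exactly_one_level(self, records_by_id):
        homo = _trunc_record("E83X", zygosity=Zygosity.HOMOZYGOUS)
        comp = dataclasses.replace(
            homo, zygosity=Zygosity.COMPOUND_HETEROZYGOUS, partner_id="H_Q426X"
        )
        assert _call_trunc(homo).klass == "severe"
        assert _call_trunc(comp, catalogue=records_by_id).klass == "moderate"

    def test_heterozygous_never_above_homozygous(self):
        order = {"mild": 0, "moderate": 1, "severe": 2}
        for change in ("Y126X", "K616X", "V720X", "W858X"):
            homo = _trunc_record(change, zygosity=Zygosity.HOMOZYGOUS)
            het = dataclasses.replace(homo, zygosity=Zygosity.HETEROZYGOUS)
            assert order[_call_trunc(het).klass] <= order[_call_trunc(homo).klass]

    def test_attenuation_floor_is_mild(self):
        rec = _subst_record("R182W", zygosity=Zygosity.HETEROZYGOUS)
        assert classify_substitution(rec, location="away").klass == "mild"


class TestClassifyAll:
    def test_matches_all_observed_phenotypes(self, records, records_by_id):
        calls = classify_all(records, evidence=reported_substitution_evidence())
        for rec in records:
            assert calls[rec.id].klass == rec.observed_phenotype.value, rec.id

    def test_narrated_cases(self, records_by_id):
        """The ten case narratives: goat W466X severe; cow W858X severe; human
        W466X comp-het mild; K616X het mild; E83X/Q426X comp-het moderate;
        V720X severe; R182W mild; G392E moderate; S505P severe; R641H moderate."""
        records = list(records_by_id.values())
        calls = classify_all(records, evidence=reported_substitution_evidence())
        human_w466x = dataclasses.replace(
            records_by_id["G_W466X"], id="H_W466X", species=Species.HUMAN,
            zygosity=Zygosity.COMPOUND_HETEROZYGOUS, shared_species=frozenset(),
        )
        extra = classify_all(records + [human_w466x],
                             evidence=reported_substitution_evidence())
        expected = {
            "G_W466X": "severe", "C_W858X": "severe", "H_W466X": "mild",
            "H_K616X": "mild", "H_E83X": "moderate", "H_Q426X": "moderate",
            "H_V720X": "severe", "H_R182W": "mild", "H_G392E": "moderate",
            "H_S505P": "severe", "H_R641H": "moderate",
        }
        for rid, klass in expected.items():
            assert extra[rid].klass == klass, rid

    def test_determinism(self, records):
        a = classify_all(records, evidence=reported_substitution_evidence())
        b = classify_all(records, evidence=reported_substitution_evidence())
        assert a == b

    def test_empty_input(self):
        assert classify_all([]) == {}

    def test_substitution_without_evidence_uses_sequence_rules(self, caplog):
        rec = _subst_record("E457Q")  # catalytic nucleophile itself
        with caplog.at_level("WARNING"):
            calls = classify_all([rec])
        assert calls[rec.id].klass == "severe"
        rec2 = _subst_record("A100V")
        assert classify_all([rec2])[rec2.id].klass == "mild"


class TestRuleTableCompleteness:
    def test_every_evidence_combination_maps_to_one_class(self):
        locations = ["direct", "close", "away"]
        destab = [True, False]
        zygosities = list(Zygosity)
        species = [Species.HUMAN, Species.COW]
        for loc, dz, zg, sp in itertools.product(locations, destab, zygosities, species):
            rec = _subst_record("G392E", zygosity=zg, species=sp)
            contacts = (ContactLoss(700, "salt_bridge", destabilizes_fold=dz),)
            call = classify_substitution(rec, contacts_lost=contacts, location=loc)
            assert call.klass in ("mild", "moderate", "severe")
            assert call.rationale
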