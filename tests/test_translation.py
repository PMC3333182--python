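"""Transcript editing, frame selection, translation and truncation extent."""
import pytest
from hypothesis import given, settings, strategies as st

from mannomap.catalogue import EventKind, MutationRecord, Species
from mannomap.structure import ActiveSiteDefinition, human_active_site
from mannomap.synthetic import SyntheticSpec, generate_transcript
from mannomap.translation import (
    MutantProteinResult,
    TranscriptModel,
    TranslationError,
    active_site_retained,
    apply_edit,
    result_from_protein_change,
    select_reading_frame,
    translate,
    translate_mutant,
    truncation_extent,
)


def _event(kind, nt_start, *, nt_end=None, ins=None, dele=None):
    return MutationRecord(
        id="e", species=Species.HUMAN, event_kind=kind,
        nt_start=nt_start, nt_end=nt_end, inserted_bases=ins, deleted_bases=dele,
        protein_ref="A", protein_pos=1,
        protein_alt="X" if kind is not EventKind.MISSENSE else "V",
    )


class TestApplyEdit:
    def test_point_substitution(self):
        # G -> T at 1-based CDS position 5 turns Trp codon TGG into TTG
        ev = _event(EventKind.NONSENSE, 5, ins="T")
        assert apply_edit("ATGTGGTAA", ev) == "ATGTTGTAA"

    def test_insertion_after_position(self):
        ev = _event(EventKind.INSERTION, 3, ins="C")
        assert apply_edit("ATGAAATAA", ev) == "ATGCAAATAA"

    def test_deletion_closed_interval(self):
        ev = _event(EventKind.DELETION, 4, nt_end=6)
        assert apply_edit("ATGAAATAA", ev) == "ATGTAA"

    def test_deleted_bases_checked_against_reference(self):
        ev = _event(EventKind.DELETION, 4, nt_end=6, dele="CCC")
        with pytest.raises(TranslationError, match="do not match"):
            apply_edit("ATGAAATAA", ev)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(TranslationError, match="outside"):
            apply_edit("ATGTAA", _event(EventKind.NONSENSE, 99, ins="T"))

    def test_coord_offset_bridges_catalogue_coordinates(self):
        ev = _event(EventKind.NONSENSE, 105, ins="T")  # catalogue coord = CDS + 100
        assert apply_edit("ATGTGGTAA", ev, coord_offset=100) == "ATGTTGTAA"

    @given(st.integers(1, 9), st.text(alphabet="ACGT", min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_length_bookkeeping(self, pos, ins):
        cds = "ATGAAACCCTAA"[:9]
        ev = _event(EventKind.INSERTION, min(pos, len(cds)), ins=ins)
        assert len(apply_edit(cds, ev)) == len(cds) + len(ins)


class TestSelectReadingFrame:
    def test_first_atg_any_offset(self):
        orf = select_reading_frame("CCATGTGGTAA")
        assert orf.seq == "ATGTGGTAA"
        assert orf.stop_reached

    def test_minimal_orf(self):
        orf = select_reading_frame("ATGTAA")
        assert orf.seq == "ATGTAA"

    def test_no_start_codon_is_an_error(self):
        with pytest.raises(TranslationError, match="no start codon"):
            select_reading_frame("CCCCCC")

    def test_no_stop_reported(self):
        orf = select_reading_frame("ATGGAAGAA")
        assert not orf.stop_reached
        assert orf.seq == "ATGGAAGAA"


class TestTranslate:
    def test_standard_code(self):
        assert translate("ATGTGGTAA").protein == "MW"

    def test_no_stop_flagged(self):
        t = translate("ATGGAAGAA")
        assert t.protein == "MEE"
        assert not t.stop_reached

    def test_tryptophan_codon(self):
        assert translate("ATGTGGTGGTAA").protein == "MWW"

    def test_non_acgt_error_names_position(self):
        with pytest.raises(TranslationError, match="position 5"):
            translate("ATGTNGTAA")


class TestTruncationExtent:
    def _result(self, stop_after, wt_len):
        return MutantProteinResult(
            mutant_seq="", is_truncated=stop_after is not None,
            stop_after_residue=stop_after,
            removed_count=0, retained_fraction=0.0, wt_len=wt_len,
        )

    def test_cow_truncation_removes_22_residues(self):
        # W858X on the 879-residue cow precursor stops after residue 857
        removed, fraction = truncation_extent(879, self._result(857, 879))
        assert removed == 22

    def test_full_length_removes_nothing(self):
        removed, fraction = truncation_extent(100, self._result(None, 100))
        assert removed == 0
        assert fraction == 1.0

    def test_arithmetic(self):
        removed, fraction = truncation_extent(10, self._result(3, 10))
        assert removed == 7
        assert fraction == pytest.approx(0.3)

    def test_negative_removed_is_invariant_violation(self):
        with pytest.raises(TranslationError):
            truncation_extent(5, self._result(10, 5))


class TestActiveSiteRetained:
    def _truncated(self, stop_after, wt_len=879):
        return MutantProteinResult(
            mutant_seq="", is_truncated=True, stop_after_residue=stop_after,
            removed_count=wt_len - stop_after, retained_fraction=stop_after / wt_len,
            wt_len=wt_len,
        )

    def test_k616x_loses_w657_only(self):
        res = active_site_retained(self._truncated(615), human_active_site())
        assert res.active_site_retained[657] is False
        assert all(res.active_site_retained[p] for p in (190, 191, 192, 390, 457, 554))
        assert res.active_site_complete is False

    def test_full_length_retains_all(self):
        full = MutantProteinResult(
            mutant_seq="", is_truncated=False, stop_after_residue=None,
            removed_count=0, retained_fraction=1.0, wt_len=879,
        )
        res = active_site_retained(full, human_active_site())
        assert res.active_site_complete is True

    def test_early_truncation_loses_all_seven(self):
        res = active_site_retained(self._truncated(125), human_active_site())
        assert not any(res.active_site_retained.values())

    def test_position_beyond_wt_length_rejected(self):
        as_def = ActiveSiteDefinition(catalytic=frozenset({457}), binding=frozenset({5000}))
        with pytest.raises(TranslationError):
            active_site_retained(self._truncated(100), as_def)


class TestTranscriptModel:
    def test_invariants(self):
        with pytest.raises(TranslationError):
            TranscriptModel(species="human", cds="ATGAAATA")  # not /3
        with pytest.raises(TranslationError):
            TranscriptModel(species="human", cds="AAAAAATAA")  # no ATG start
        with pytest.raises(TranslationError):
            TranscriptModel(species="human", cds="ATGAAAAAA")  # no stop end


class TestTranslateMutant:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_wild_type_round_trip(self, seed):
        # translate(select_reading_frame(cds)) reproduces the stored protein
        spec = SyntheticSpec(seed=seed, n_residues=80,
                             active_site_positions=frozenset({30, 40, 50}))
        transcript, protein = generate_transcript(spec)
        orf = select_reading_frame(transcript.cds)
        assert translate(orf.seq).protein == protein

    @pytest.mark.parametrize("ins_len", [1, 2, 4, 5])
    def test_frameshift_insertion_diverges_then_truncates(self, ins_len):
        spec = SyntheticSpec(seed=5, n_residues=150,
                             active_site_positions=frozenset({30, 40, 50}))
        transcript, protein = generate_transcript(spec)
        ev = _event(EventKind.INSERTION, 90, ins="A" * ins_len)  # inside codon 30
        res = translate_mutant(transcript, ev)
        # prefix before the insertion codon is preserved, divergence at/after it
        assert res.mutant_seq[:29] == protein[:29]
        assert res.is_truncated or res.non_stop

    def test_monotonicity_earlier_stop_removes_more(self):
        spec = SyntheticSpec(seed=6, n_residues=100,
                             active_site_positions=frozenset({30, 40, 50}))
        transcript, protein = generate_transcript(spec)
        removed = []
        for codon in (20, 50, 80):
            nt = 3 * codon - 2
            ev = MutationRecord(
                id=f"n{codon}", species=Species.HUMAN, event_kind=EventKind.DELETION,
                nt_start=nt, nt_end=nt,  # 1-nt deletion: frameshift
                protein_ref=protein[codon - 1], protein_pos=codon, protein_alt="X",
            )
            res = translate_mutant(transcript, ev)
            removed.append(res.removed_count)
        assert removed[0] >= removed[1] >= removed[2]


class TestResultFromProteinChange:
    def test_truncating_record(self, records_by_id):
        res = result_from_protein_change(records_by_id["C_W858X"], 879, human_active_site())
        assert res.stop_after_residue == 857
        assert res.removed_count == 22
        assert res.active_site_complete is True

    def test_substitution_at_active_site_marks_it_lost(self):
        rec = MutationRecord(id="s", species=Species.HUMAN, event_kind=EventKind.MISSENSE,
                             protein_ref="E", protein_pos=457, protein_alt="Q")
        res = result_from_protein_change(rec, 879, human_active_site())
        assert res.active_site_retained[457] is False
        assert res.active_site_complete is False
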