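"""Window matching, evidence resolution and genotype assembly."""

import pytest

from hmwgs import (
    AuxiliaryEvidence,
    CallConfig,
    SimConfig,
    STANDARD_CULTIVARS,
    assemble_genotype,
    call_line,
    make_genotype,
    match_peaks,
    resolve_ambiguities,
    simulate_auxiliary_evidence,
    simulate_chromatogram,
)
from hmwgs.calling import (
    FLAG_A1_NULL,
    FLAG_ATYPICAL,
    FLAG_BX_NULL,
    FLAG_HET,
    FLAG_UNRESOLVED_7,
    STATUS_GEL,
    STATUS_LINKAGE,
    STATUS_PCR,
    STATUS_UNAMBIGUOUS,
)
from hmwgs.peaks import Peak
from hmwgs.simulate import PCR_POSITIVE, PCR_UNTESTED

from conftest import SEED


def peak_at(rt, merged=False):
    return Peak(apex_rt=rt, area=1000.0, height=33000.0,
                left=rt - 0.05, right=rt + 0.05, merged=merged)


class TestMatchPeaks:
    @pytest.mark.parametrize("apex,expected", [
        (5.37, {"1Ax1"}),
        (3.74, {"1By8*", "1By9", "1By15", "1By18"}),
        (4.67, {"1Bx7", "1Bx7OE", "1Bx14"}),
        (4.71, {"1Bx17"}),
        (2.97, {"1Dy12"}),
        (1.00, set()),
    ])
    def test_candidate_sets(self, library, apex, expected):
        (a,) = match_peaks([peak_at(apex)], library)
        assert set(a.candidates) == expected

    def test_two_peaks_claiming_one_reference_resolved_by_distance(self, library):
        a1, a2 = match_peaks([peak_at(4.44), peak_at(4.46)], library)
        assert a1.candidates == frozenset({"1Dx2"})
        assert a2.candidates == frozenset()
        assert "outcompeted" in a2.note

    def test_merged_peak_keeps_all_window_hits(self, library):
        (a,) = match_peaks([peak_at(2.985, merged=True)], library)
        assert a.candidates == frozenset({"1Dy10", "1Dy12"})


class TestResolveAmbiguities:
    def test_linkage_infers_1by18_from_unambiguous_1bx17(self, library):
        assignments = match_peaks([peak_at(3.73), peak_at(4.71)], library)
        calls, _ = resolve_ambiguities(assignments, None, library)
        by = {c.status: c for c in calls}
        assert by[STATUS_LINKAGE].subunit == "1By18"
        assert by[STATUS_UNAMBIGUOUS].subunit == "1Bx17"

    def test_gel_band_resolves_by_cluster(self, library):
        assignments = match_peaks([peak_at(3.75)], library)
        ev = AuxiliaryEvidence(gel_confirmed=frozenset({"1By9"}))
        (call,), _ = resolve_ambiguities(assignments, ev, library)
        assert call.subunit == "1By9" and call.status == STATUS_GEL

    def test_pcr_splits_7_from_7oe(self, library):
        assignments = match_peaks([peak_at(4.63)], library)
        ev = AuxiliaryEvidence(gel_confirmed=frozenset({"1Bx7OE"}),
                               pcr_7oe=PCR_POSITIVE)
        (call,), _ = resolve_ambiguities(assignments, ev, library)
        assert call.subunit == "1Bx7OE" and call.status == STATUS_PCR

    def test_pcr_untested_leaves_pair_unresolved(self, library):
        assignments = match_peaks([peak_at(4.67)], library)
        ev = AuxiliaryEvidence(gel_confirmed=frozenset({"1Bx7"}),
                               pcr_7oe=PCR_UNTESTED)
        (call,), _ = resolve_ambiguities(assignments, ev, library)
        assert call.candidates == frozenset({"1Bx7", "1Bx7OE"})
        assert not call.resolved

    def test_gel_conflict_is_reported_not_overridden(self, library):
        assignments = match_peaks([peak_at(2.97)], library)
        ev = AuxiliaryEvidence(gel_confirmed=frozenset({"1By15"}))
        (call,), notes = resolve_ambiguities(assignments, ev, library)
        assert call.subunit == "1Dy12"
        assert any("conflict" in n for n in notes)

    def test_evidence_never_changes_an_unambiguous_call(self, library, zero_noise):
        """Adding gel/PCR evidence only shrinks candidate sets."""
        from hmwgs.peaks import correct_baseline, detect_peaks
        for g in STANDARD_CULTIVARS.values():
            chrom = simulate_chromatogram(g, library, zero_noise, seed=SEED)
            peaks = detect_peaks(correct_baseline(chrom))
            bare, _ = resolve_ambiguities(match_peaks(peaks, library), None, library)
            ev = simulate_auxiliary_evidence(g, library)
            full, _ = resolve_ambiguities(match_peaks(peaks, library), ev, library)
            for b, f in zip(bare, full):
                if b.status == STATUS_UNAMBIGUOUS:
                    assert f.candidates == b.candidates
                else:
                    assert f.candidates <= b.candidates


class TestAssembleGenotype:
    def _calls(self, library, names):
        assignments = match_peaks(
            [peak_at(library.get(n).mean_rt) for n in names], library)
        calls, _ = resolve_ambiguities(
            assignments, None, library)
        return calls

    def test_insignia_symbols_without_flags(self, library):
        calls = self._calls(library, ["1Ax1", "1Bx20x", "1By20y", "1Dx5", "1Dy10"])
        g = assemble_genotype("Insignia", calls, library)
        assert g.symbols == {"Glu-A1": "Glu-A1a", "Glu-B1": "Glu-B1e",
                             "Glu-D1": "Glu-D1d"}
        assert g.flags == frozenset()

    def test_null_partners_get_null_flags_and_single_subunit_symbol(self, library):
        ev = AuxiliaryEvidence(gel_confirmed=frozenset({"1By15"}))
        assignments = match_peaks(
            [peak_at(library.get(n).mean_rt) for n in ["1By15", "1Dx2", "1Dy12"]],
            library)
        calls, _ = resolve_ambiguities(assignments, ev, library)
        g = assemble_genotype("nulls", calls, library)
        assert {FLAG_A1_NULL, FLAG_BX_NULL} <= g.flags
        assert g.symbols["Glu-B1"] == "Glu-B1-2e"

    def test_heterozygous_glu_d1_reports_both_alleles(self, library):
        calls = self._calls(library, ["1Ax1", "1Bx7", "1By8",
                                      "1Dx5", "1Dy10", "1Dx2", "1Dy12"])
        g = assemble_genotype("het", calls, library)
        assert FLAG_HET in g.flags
        assert g.symbols["Glu-D1"] == "Glu-D1a/Glu-D1d"

    def test_uncatalogued_combination_is_flagged(self, library):
        calls = self._calls(library, ["1Ax1", "1Bx7", "1By8", "1Dx5", "1Dy12"])
        g = assemble_genotype("odd", calls, library)
        assert g.symbols["Glu-D1"] == "unknown"
        assert "unknown_combination" in g.flags


class TestCallLine:
    def test_cheyenne_end_to_end(self, library, zero_noise):
        g = STANDARD_CULTIVARS["Cheyenne"]
        chrom = simulate_chromatogram(g, library, zero_noise, seed=SEED)
        call = call_line(chrom, simulate_auxiliary_evidence(g, library), library)
        assert call.subunits["Glu-A1"] == frozenset({"1Ax2*"})
        assert call.subunits["Glu-B1"] == frozenset({"1Bx7", "1By9"})
        assert call.subunits["Glu-D1"] == frozenset({"1Dx5", "1Dy10"})
        assert call.symbols["Glu-B1"] == "Glu-B1c"

    def test_glenlea_without_pcr_flags_7_7oe(self, library, zero_noise):
        g = STANDARD_CULTIVARS["Glenlea"]
        chrom = simulate_chromatogram(g, library, zero_noise, seed=SEED)
        ev = AuxiliaryEvidence(gel_confirmed=frozenset({"1Bx7OE", "1By8*"}),
                               pcr_7oe=PCR_UNTESTED)
        call = call_line(chrom, ev, library)
        assert FLAG_UNRESOLVED_7 in call.flags
        assert call.displays["Glu-B1"] == "7/7OE + 8*"

    def test_empty_trace_gets_null_and_atypical_flags(self, library, zero_noise):
        chrom = simulate_chromatogram(make_genotype("blank"), library,
                                      zero_noise, seed=SEED)
        call = call_line(chrom, None, library)
        assert FLAG_A1_NULL in call.flags
        assert FLAG_ATYPICAL in call.flags
        assert call.symbols["Glu-A1"] == "Glu-A1c"

    def test_every_called_subunit_corresponds_to_a_detected_peak(self, library):
        """No fabrication: subunit calls map 1:1 onto peaks."""
        g = STANDARD_CULTIVARS["Joongmo 2008"]  # includes linkage-implied 1By18
        chrom = simulate_chromatogram(g, library, SimConfig(), seed=SEED)
        call = call_line(chrom, simulate_auxiliary_evidence(g, library), library)
        called = set().union(*call.subunits.values())
        assert called == g.subunits
        resolved_calls = [c for c in call.calls if c.resolved]
        assert len(resolved_calls) == len(called)
        for c in resolved_calls:
            lo, hi = library.rt_window(c.subunit, 3.0, 0.21)
            assert lo <= c.apex_rt <= hi

    def test_area_ratio_fallback_identifies_7oe(self, library, zero_noise):
        g = STANDARD_CULTIVARS["Glenlea"]  # 1Bx7OE rendered at double area
        chrom = simulate_chromatogram(g, library, zero_noise, seed=SEED)
        ev = AuxiliaryEvidence(gel_confirmed=frozenset({"1Bx7OE", "1By8*"}),
                               pcr_7oe=PCR_UNTESTED)
        cfg = CallConfig(use_area_ratio=True)
        call = call_line(chrom, ev, library, cfg)
        assert call.subunits["Glu-B1"] == frozenset({"1Bx7OE", "1By8*"})
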