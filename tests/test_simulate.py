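"""Synthetic chromatogram generator: shapes, determinism, cohorts."""

import numpy as np
import pytest

from hmwgs import (
    AuxiliaryEvidence,
    CohortSpec,
    SimConfig,
    STANDARD_CULTIVARS,
    assign_peaks_to_subunits,
    cohort_genotypes,
    correct_baseline,
    detect_peaks,
    make_genotype,
    simulate_auxiliary_evidence,
    simulate_chromatogram,
    simulate_cohort,
    simulate_replicates,
    truth_table,
)
from hmwgs.reference import UnknownSubunitError
from hmwgs.simulate import CohortSpecError, PCR_NEGATIVE, PCR_POSITIVE, PCR_UNTESTED

from conftest import SEED


class TestSingleTrace:
    def test_baekjoong_zero_noise_apexes_at_library_means(self, library, zero_noise):
        chrom = simulate_chromatogram(
            STANDARD_CULTIVARS["Baekjoong"], library, zero_noise, seed=SEED)
        peaks = detect_peaks(chrom)
        apexes = sorted(p.apex_rt for p in peaks)
        assert apexes == pytest.approx([2.97, 3.96, 4.23, 4.31, 5.24], abs=0.002)

    def test_empty_genotype_gives_no_peaks(self, library):
        chrom = simulate_chromatogram(make_genotype("blank"), library,
                                      SimConfig(), seed=SEED)
        assert detect_peaks(correct_baseline(chrom)) == []

    def test_same_seed_reproduces_trace_exactly(self, library):
        g = STANDARD_CULTIVARS["Chinese Spring"]
        a = simulate_chromatogram(g, library, SimConfig(), seed=SEED)
        b = simulate_chromatogram(g, library, SimConfig(), seed=SEED)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_unknown_subunit_raises(self, library):
        with pytest.raises(UnknownSubunitError):
            simulate_chromatogram(make_genotype("bad", b1=["1Bx99"]),
                                  library, SimConfig(), seed=SEED)

    def test_area_conservation_without_noise(self, library):
        """Integral of (trace - baseline) equals the injected total area."""
        cfg = SimConfig(noise_sd=0.0)
        g = STANDARD_CULTIVARS["Glenlea"]  # includes the 2x 1Bx7OE scale
        chrom = simulate_chromatogram(g, library, cfg, seed=SEED)
        integral = np.trapezoid(
            chrom.intensity - cfg.baseline_slope * chrom.time, chrom.time)
        expected = cfg.base_area * (len(g.subunits) + 1)  # 7OE counts twice
        assert integral == pytest.approx(expected, rel=0.005)

    def test_heterozygous_second_allele_at_half_area(self, library, zero_noise):
        g = make_genotype("het", a1=["1Ax2*"], b1=["1Bx7", "1By8"],
                          d1=["1Dx2", "1Dy12"],
                          het_a1=frozenset({"1Ax1"}))
        chrom = simulate_chromatogram(g, library, zero_noise, seed=SEED)
        peaks = detect_peaks(chrom)
        areas = {name: area for name, _, area in
                 assign_peaks_to_subunits(peaks, g.all_subunits, library)}
        assert len(peaks) == 6
        assert areas["1Ax1"] == pytest.approx(0.5 * areas["1Ax2*"], rel=0.02)


class TestReplicates:
    def test_fewer_than_two_replicates_rejected(self, library):
        with pytest.raises(ValueError):
            simulate_replicates(STANDARD_CULTIVARS["Anbaek"], 1, library)

    def test_zero_cv_replicates_have_identical_apexes(self, library, zero_noise):
        reps = simulate_replicates(STANDARD_CULTIVARS["Chinese Spring"], 2,
                                   library, zero_noise, seed=SEED)
        apexes = [sorted(p.apex_rt for p in detect_peaks(r)) for r in reps]
        assert apexes[0] == pytest.approx(apexes[1], abs=1e-9)

    def test_each_replicate_has_full_peak_complement(self, library):
        g = STANDARD_CULTIVARS["Chinese Spring"]
        reps = simulate_replicates(g, 10, library, SimConfig(), seed=SEED)
        for r in reps:
            assert len(detect_peaks(correct_baseline(r))) == 4

    def test_apex_rsd_recovers_configured_jitter(self, library):
        """Detected-apex RSD over 200 replicates converges to the configured
        within-line RT CV (20% relative)."""
        cfg = SimConfig()
        g = make_genotype("one", d1=["1Dy12"])
        reps = simulate_replicates(g, 200, library, cfg, seed=SEED)
        apexes = np.array([detect_peaks(correct_baseline(r))[0].apex_rt
                           for r in reps])
        rsd = 100 * apexes.std(ddof=1) / apexes.mean()
        assert rsd == pytest.approx(cfg.within_line_rt_cv_pct, rel=0.20)


class TestAuxiliaryEvidence:
    def test_glenlea_gel_and_pcr(self, library):
        ev = simulate_auxiliary_evidence(STANDARD_CULTIVARS["Glenlea"], library)
        assert {"1Bx7OE", "1By8*"} <= set(ev.gel_confirmed)
        assert ev.pcr_7oe == PCR_POSITIVE

    def test_chinese_spring_pcr_negative(self, library):
        ev = simulate_auxiliary_evidence(
            STANDARD_CULTIVARS["Chinese Spring"], library)
        assert ev.pcr_7oe == PCR_NEGATIVE

    def test_line_without_bx7_variants_untested(self, library):
        ev = simulate_auxiliary_evidence(
            STANDARD_CULTIVARS["Joongmo 2008"], library)
        assert ev.pcr_7oe == PCR_UNTESTED

    def test_gel_only_covers_gel_resolvable_subunits(self, library):
        ev = simulate_auxiliary_evidence(STANDARD_CULTIVARS["Insignia"], library)
        assert ev.gel_confirmed == frozenset()

    def test_invalid_pcr_state_rejected(self):
        with pytest.raises(ValueError):
            AuxiliaryEvidence(pcr_7oe="maybe")


class TestCohort:
    def test_truth_marginals_match_requested_counts_exactly(self, library):
        spec = CohortSpec.from_reference_counts(library)
        genos = cohort_genotypes(spec, seed=SEED)
        assert len(genos) == 1787
        for locus in ("Glu-A1", "Glu-B1", "Glu-D1"):
            observed = {}
            for g in genos:
                key = g.locus_subunits(locus)
                observed[key] = observed.get(key, 0) + 1
            assert observed == dict(spec.allele_counts[locus])

    def test_single_line_cohort(self, library):
        spec = CohortSpec(genotypes=[STANDARD_CULTIVARS["Cheyenne"]])
        lines = list(simulate_cohort(spec, library, SimConfig(), seed=SEED))
        assert len(lines) == 1
        assert lines[0].evidence.pcr_7oe == PCR_NEGATIVE

    def test_inconsistent_locus_totals_rejected(self):
        with pytest.raises(CohortSpecError, match="same cohort size"):
            CohortSpec(allele_counts={
                "Glu-A1": {frozenset({"1Ax1"}): 2},
                "Glu-B1": {frozenset({"1Bx7", "1By8"}): 1},
                "Glu-D1": {frozenset({"1Dx2", "1Dy12"}): 2},
            })

    def test_cohort_generation_is_seed_deterministic(self, library):
        spec = CohortSpec(allele_counts={
            "Glu-A1": {frozenset({"1Ax1"}): 2, frozenset(): 1},
            "Glu-B1": {frozenset({"1Bx7", "1By8"}): 3},
            "Glu-D1": {frozenset({"1Dx5", "1Dy10"}): 3},
        })
        a = truth_table(cohort_genotypes(spec, seed=SEED), library)
        b = truth_table(cohort_genotypes(spec, seed=SEED), library)
        assert a.equals(b)

    def test_truth_table_symbols(self, library):
        spec = CohortSpec(genotypes=[STANDARD_CULTIVARS["Insignia"]])
        row = truth_table(cohort_genotypes(spec, seed=SEED), library).iloc[0]
        assert (row.a1_symbol, row.b1_symbol, row.d1_symbol) == \
            ("Glu-A1a", "Glu-B1e", "Glu-D1d")


class TestSimConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"dt": 0.0}, {"peak_sigma": 0.001}, {"area_cv_pct": -1},
        {"t_end": -1.0},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)
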