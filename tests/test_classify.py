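"""The phase-classification decision tree and template matching."""

import numpy as np
import pytest

from carbphase import (
    BUILTIN_TEMPLATES,
    ClassificationThresholds,
    ConfigError,
    CoverageError,
    DomainError,
    PeakFit,
    classify_spectrum,
    format_report,
    match_templates,
)
from carbphase.spectra_io import LATTICE_WINDOW, Spectrum
from carbphase.synthetic_data import SynthesisSpec, make_template_spectrum


def _peak(center, fwhm=8.0, height=0.3):
    return PeakFit(center=center, height=height, fwhm=fwhm, eta=0.5, rmse=0.0,
                   window=LATTICE_WINDOW)


class TestMatchTemplates:
    def test_perfect_calcite_match_scores_one(self):
        crystalline = [BUILTIN_TEMPLATES["calcite"], BUILTIN_TEMPLATES["aragonite"]]
        ranked = match_templates([_peak(150.0), _peak(280.0)], crystalline)
        assert ranked[0] == ("calcite", pytest.approx(1.0))

    def test_calcite_peaks_score_above_aragonite(self):
        # 280 cm^-1 is clearly different from the aragonite lattice set
        crystalline = [BUILTIN_TEMPLATES["calcite"], BUILTIN_TEMPLATES["aragonite"]]
        ranked = dict(match_templates([_peak(150.0), _peak(280.0)], crystalline))
        assert ranked["calcite"] > ranked["aragonite"]

    def test_no_observed_peaks_is_an_error(self):
        with pytest.raises(DomainError):
            match_templates([], [BUILTIN_TEMPLATES["calcite"]])

    def test_no_templates_is_an_error(self):
        with pytest.raises(ConfigError):
            match_templates([_peak(150.0)], [])

    def test_nu4_agreement_breaks_near_ties(self):
        crystalline = [BUILTIN_TEMPLATES["calcite"], BUILTIN_TEMPLATES["aragonite"]]
        # a single ~151 lattice peak matches both sets equally; a nu4 band
        # at 716 sits within tolerance of calcite's 712 but not of
        # aragonite's 705, so the nu4 term decides
        ranked = match_templates([_peak(151.0)], crystalline, nu4=_peak(716.0, 5.0, 0.08))
        assert ranked[0][0] == "calcite"


class TestDecisionTree:
    def test_noiseless_templates_all_correct(self, noiseless_results):
        for phase, result in noiseless_results.items():
            assert result.phase == phase

    def test_acc_gets_mg_ambiguity_flag(self, noiseless_results):
        # width alone cannot separate ACC from high-Mg calcite
        assert "mg_unknown_ambiguity" in noiseless_results["acc"].flags

    def test_crystalline_iff_distinct_lattice_peaks(self, noiseless_results):
        for result in noiseless_results.values():
            lat = result.evidence["lattice"]
            assert result.crystalline == (lat.verdict == "distinct_peaks")

    def test_known_low_mg_resolves_ambiguity_to_acc(self):
        s = make_template_spectrum(SynthesisSpec(phase="acc"))
        result = classify_spectrum(s, preprocess=True, mg_mol_percent=1.0)
        assert result.phase == "acc"
        assert "mg_unknown_ambiguity" not in result.flags

    def test_known_high_mg_resolves_to_high_mg_calcite(self):
        s = make_template_spectrum(SynthesisSpec(phase="acc"))
        result = classify_spectrum(s, preprocess=True, mg_mol_percent=10.0)
        assert result.phase == "high_mg_calcite"

    def test_dispute_case_lattice_peaks_plus_broad_nu1(self):
        # distinct 150/280 lattice peaks with nu1 FWHM 24: crystalline,
        # read as disorder-broadened (high-Mg) calcite, never amorphous
        s = make_template_spectrum(SynthesisSpec(phase="calcite", nu1_fwhm_override=24.0))
        result = classify_spectrum(s, preprocess=True)
        assert result.phase == "high_mg_calcite"
        assert result.crystalline is True

    def test_narrow_nu1_without_lattice_is_indeterminate(self):
        # contradictory evidence: never silently call a phase
        s = make_template_spectrum(SynthesisSpec(phase="acc", nu1_fwhm_override=10.0))
        result = classify_spectrum(s, preprocess=True)
        assert result.phase == "indeterminate"

    def test_no_nu1_band_is_indeterminate_low_snr(self):
        rng = np.random.default_rng(3)
        x = np.arange(100.0, 1301.0, 1.0)
        s = Spectrum(x, rng.normal(0.0, 0.01, x.size))
        result = classify_spectrum(s, noise_sigma=0.01)
        assert result.phase == "indeterminate"
        assert "low_snr" in result.flags

    def test_missing_window_coverage_raises(self):
        x = np.arange(100.0, 1051.0, 1.0)
        with pytest.raises(CoverageError) as err:
            classify_spectrum(Spectrum(x, np.zeros(x.size) + 1e-6))
        assert "nu1" in err.value.missing

    def test_report_is_stable_text(self, noiseless_results):
        text = format_report(noiseless_results["calcite"], source="calcite.csv")
        assert text == format_report(noiseless_results["calcite"], source="calcite.csv")
        assert "phase: calcite" in text
        assert "lattice: verdict=distinct_peaks" in text


class TestRobustnessProperties:
    def test_noisy_phase_calls_at_least_95_percent_correct(self, noisy_phase_calls):
        for phase, calls in noisy_phase_calls.items():
            accuracy = np.mean([c == phase for c in calls])
            assert accuracy >= 0.95, f"{phase}: {accuracy:.3f}"

    @pytest.mark.parametrize("nu1_fwhm", [5.0, 12.0, 20.0, 21.0, 28.0, 40.0, 60.0])
    def test_lattice_peak_supremacy(self, nu1_fwhm):
        # no spectrum with distinct lattice peaks is ever called ACC,
        # whatever its nu1 width
        s = make_template_spectrum(
            SynthesisSpec(phase="calcite", nu1_fwhm_override=nu1_fwhm)
        )
        result = classify_spectrum(s, preprocess=True)
        assert result.phase != "acc"
        assert result.crystalline is True

    @pytest.mark.parametrize("background", [("linear", 1.0), ("linear", 5.0),
                                            ("quadratic", 5.0)])
    def test_fluorescence_invariance(self, background, noiseless_results):
        # any monotone smooth background up to 5x the nu1 height changes
        # no phase call on the noiseless template suite
        for phase, clean in noiseless_results.items():
            s = make_template_spectrum(SynthesisSpec(phase=phase, background=background))
            result = classify_spectrum(s, preprocess=True)
            assert result.phase == clean.phase

    def test_strict_threshold_inequality(self):
        # a fitted nu1 FWHM of exactly the threshold is not "broad"
        s = make_template_spectrum(SynthesisSpec(phase="acc", nu1_fwhm_override=20.0))
        result = classify_spectrum(s, preprocess=True)
        assert result.phase != "acc"

    def test_configurable_threshold_moves_boundary(self):
        thresholds = ClassificationThresholds(acc_fwhm_min=30.0)
        s = make_template_spectrum(SynthesisSpec(phase="acc"))  # nu1 FWHM 28
        result = classify_spectrum(s, preprocess=True, thresholds=thresholds)
        assert result.phase == "indeterminate"
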