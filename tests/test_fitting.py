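"""Chemical-shift referencing, baselines and Lorentzian deconvolution."""

import numpy as np
import pytest

from uremiq.errors import FitError, ReferencingError
from uremiq.fitting import (
    FitResult,
    LorentzianPeak,
    baseline_correct,
    build_regions,
    fit_region,
    fit_spectrum,
    integrate_fit,
    reference_shift,
)
from uremiq.library import ResonanceGroup
from uremiq.lineshapes import lorentzian_profile
from uremiq.simulate import AcquisitionParams, PatientSample, simulate_spectrum
from uremiq.spectrum import Spectrum


def _singlet(center, name="x", n_protons=1, quantifiable=True):
    return ResonanceGroup(name, center, "singlet", 0.0, n_protons, quantifiable)


def _spectrum_with_peaks(peaks, lo=-1.0, hi=2.0, pts=12001, baseline=None, noise=0.0, seed=0):
    axis = np.linspace(hi, lo, pts)
    y = np.zeros_like(axis)
    for center, fwhm, area in peaks:
        y += lorentzian_profile(center, fwhm, area, axis)
    if baseline is not None:
        y += baseline(axis)
    if noise:
        y += np.random.default_rng(seed).normal(0, noise, axis.size)
    return Spectrum(axis, y)


class TestReferencing:
    def test_translation_restores_zero(self, library, quiet_acq, panel_truth):
        sample = PatientSample("P1", panel_truth, egfr=20.0)
        spec = simulate_spectrum(sample, "ultrafiltration", library, quiet_acq, seed=0)
        shifted = spec.shifted(+0.01)
        restored = reference_shift(shifted)
        sl = restored.window(-0.01, 0.01)
        peak_ppm = restored.ppm[sl][np.argmax(restored.intensity[sl])]
        assert abs(peak_ppm) <= restored.step

    def test_idempotent_within_one_step(self, library, quiet_acq, panel_truth):
        sample = PatientSample("P1", panel_truth, egfr=20.0)
        spec = simulate_spectrum(sample, "ultrafiltration", library, quiet_acq, seed=0)
        once = reference_shift(spec)
        twice = reference_shift(once)
        assert abs(once.ppm[0] - twice.ppm[0]) <= once.step

    def test_pca_global_shift_recovered(self, library, acq, panel_truth):
        """The random PCA axis shift is undone: TSP back at 0.00 and the
        metabolite lines back at their library positions."""
        sample = PatientSample("P1", panel_truth, egfr=20.0)
        spec = simulate_spectrum(sample, "PCA", library, acq, seed=42)
        applied = float(spec.meta["shift_offset_ppm"])
        assert applied != 0.0
        restored = reference_shift(spec)
        center = library["creatinine"].quantifiable_group.center_shift
        sl = restored.window(center - 0.015, center + 0.015)
        peak_ppm = restored.ppm[sl][np.argmax(restored.intensity[sl])]
        assert abs(peak_ppm - center) < 3.0 * restored.step

    def test_no_reference_peak_raises(self):
        spec = _spectrum_with_peaks([], noise=1.0)
        with pytest.raises(ReferencingError):
            reference_shift(spec)


class TestBaseline:
    def test_constant_offset_removed(self):
        spec = _spectrum_with_peaks([], baseline=lambda x: np.full_like(x, 55.0))
        corrected, coeffs = baseline_correct(spec, (-0.5, 0.5))
        assert np.allclose(corrected.intensity, 0.0, atol=1e-9)
        assert coeffs[-1] == pytest.approx(55.0)

    def test_zero_trace_stays_zero(self):
        spec = _spectrum_with_peaks([])
        corrected, _ = baseline_correct(spec, (-0.5, 0.5))
        assert not corrected.intensity.any()

    def test_sloped_baseline_under_peak(self):
        """Area from direct integration after correction is within 1% of
        truth for a Lorentzian sitting on a linear ramp."""
        area = 30.0
        spec = _spectrum_with_peaks(
            [(0.5, 0.004, area)], baseline=lambda x: 100.0 + 40.0 * x
        )
        corrected, _ = baseline_correct(spec, (0.5 - 0.4, 0.5 + 0.4), flank_ppm=0.02)
        got = float(np.trapezoid(corrected.intensity[::-1], corrected.ppm[::-1]))
        assert got == pytest.approx(area, rel=1e-2)

    def test_too_narrow_region_rejected(self):
        spec = _spectrum_with_peaks([])
        with pytest.raises(FitError):
            baseline_correct(spec, (0.0, 0.001))


class TestFitRegion:
    def test_single_noiseless_lorentzian_recovery(self):
        center, fwhm, area = 1.0, 0.003, 12.0
        spec = _spectrum_with_peaks([(center, fwhm, area)])
        res = fit_region(spec, (0.8, 1.2), [_singlet(1.0)])
        assert res.converged
        peak = res.peaks[0]
        assert peak.center == pytest.approx(center, abs=1e-6)
        assert peak.fwhm == pytest.approx(fwhm, rel=1e-6)
        assert peak.area == pytest.approx(area, rel=1e-6)

    def test_overlapping_peaks_resolved_jointly(self):
        """Two singlets half a linewidth apart, noise off: joint fit
        attributes the areas within 1%."""
        fwhm = 0.004
        a1, a2 = 10.0, 4.0
        c1 = 1.0
        c2 = c1 + 0.5 * fwhm
        spec = _spectrum_with_peaks([(c1, fwhm, a1), (c2, fwhm, a2)])
        groups = [_singlet(c1, "m1"), _singlet(c2, "m2")]
        res = fit_region(spec, (0.8, 1.2), groups)
        assert res.converged
        got1 = integrate_fit(res, "m1")
        got2 = integrate_fit(res, "m2")
        assert got1 == pytest.approx(a1, rel=1e-2)
        assert got2 == pytest.approx(a2, rel=1e-2)

    def test_noise_only_region_converges_to_zero(self):
        spec = _spectrum_with_peaks([], noise=5.0, seed=3)
        res = fit_region(spec, (0.8, 1.2), [_singlet(1.0)])
        assert res.converged
        total = sum(p.area for p in res.peaks)
        # statistically consistent with zero: below ~3 noise-equivalent areas
        assert total < 3.3 * 5.0 * np.pi / 2 * 0.0024
        assert res.residual_rms == pytest.approx(5.0, rel=0.2)

    def test_constrained_ratios_hold_for_triplet(self):
        g = ResonanceGroup("m", 1.0, "triplet", 7.0, 2, True)
        spec = Spectrum(
            np.linspace(1.3, 0.7, 4001),
            np.zeros(4001),
        )
        from uremiq.lineshapes import multiplet_profile

        spec.intensity += multiplet_profile(spec.ppm, g, 20.0, 500.0, 0.003)
        res = fit_region(spec, (0.9, 1.1), [g], spectrometer_freq=500.0)
        areas = sorted(p.area for p in res.peaks)
        assert areas[2] == pytest.approx(2.0 * areas[0], rel=1e-6)
        assert integrate_fit(res, "m") == pytest.approx(20.0, rel=1e-6)

    def test_ascending_axis_input_is_normalized(self):
        center, fwhm, area = 1.0, 0.003, 12.0
        axis = np.linspace(0.5, 1.5, 6001)  # ascending
        y = lorentzian_profile(center, fwhm, area, axis)
        spec = Spectrum(axis, y)
        assert spec.ppm[0] > spec.ppm[-1]  # normalized on construction
        res = fit_region(spec, (0.8, 1.2), [_singlet(1.0)])
        assert integrate_fit(res, "x") == pytest.approx(area, rel=1e-6)

    def test_expected_line_outside_region_rejected(self):
        spec = _spectrum_with_peaks([(1.0, 0.003, 5.0)])
        with pytest.raises(FitError):
            fit_region(spec, (0.8, 1.2), [_singlet(1.5)])


class TestIntegrateFit:
    def _result(self, converged=True):
        peaks = [
            LorentzianPeak("m", 1.0, i, 1.0, 0.003, a, True)
            for i, a in enumerate([1.0, 2.0, 1.0])
        ]
        return FitResult((0.9, 1.1), peaks, (0.0, 0.0), 0.1, converged)

    def test_sums_quantifiable_line_areas(self):
        assert integrate_fit(self._result(), "m") == pytest.approx(4.0)

    def test_non_converged_raises(self):
        with pytest.raises(FitError):
            integrate_fit(self._result(converged=False), "m")

    def test_absent_metabolite_raises(self):
        with pytest.raises(FitError):
            integrate_fit(self._result(), "other")


class TestRegions:
    def test_merging_joins_overlapping_multiplets(self):
        groups = [_singlet(1.00, "a"), _singlet(1.05, "b"), _singlet(2.0, "c")]
        regions = build_regions(groups, 500.0, pad=0.06)
        assert len(regions) == 2
        (lo1, hi1, gs1), (lo2, hi2, gs2) = regions
        assert {g.metabolite_id for g in gs1} == {"a", "b"}
        assert {g.metabolite_id for g in gs2} == {"c"}
        assert lo1 == pytest.approx(0.94) and hi1 == pytest.approx(1.11)


class TestNoiseScaling:
    def test_area_scatter_grows_with_noise(self, library, quiet_acq):
        """SD of the recovered area across seeds is monotone in noise_sd."""
        spreads = []
        for noise in (50.0, 400.0, 3200.0):
            areas = []
            for seed in range(6):
                params = AcquisitionParams(noise_sd=noise, baseline_amplitude=0.0)
                sample = PatientSample("P1", {"creatinine": 300.0})
                spec = simulate_spectrum(sample, "ultrafiltration", library, params, seed=seed)
                fit = fit_spectrum(spec, library)
                areas.append(fit.areas["creatinine"])
            spreads.append(np.std(areas))
        assert spreads[0] < spreads[1] < spreads[2]


def test_fit_spectrum_quantifies_visible_panel(library, acq, panel_truth):
    sample = PatientSample("P1", panel_truth, egfr=20.0)
    spec = simulate_spectrum(sample, "ultrafiltration", library, acq, seed=9)
    fit = fit_spectrum(spec, library)
    assert fit.all_converged
    assert fit.tsp_area > 0
    assert "hippuric acid" not in fit.areas  # invisible in the ultrafiltrate
    assert fit.areas["creatinine"] == pytest.approx(
        acq.response * 3 * panel_truth["creatinine"], rel=0.02
    )
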